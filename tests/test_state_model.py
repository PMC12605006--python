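import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from helixstate import (
    DistanceMetricSpec,
    FitError,
    MetricSeries,
    ParameterError,
    ReplicaSummary,
    RmsdMetricSpec,
    SelectionSpec,
    SkewNormalFit,
    StateCriterion,
    StateSeries,
    classify_frames,
    compute_metric_series,
    dwell_times,
    fit_skew_normal_cutoff,
    occupancy,
    reached_active,
    skew_normal_mean,
    summarize_replica,
)
from helixstate.state_model import series_to_tsv
from helixstate.structure_io import Trajectory


def distance_criterion(cutoff=4.6):
    metric = DistanceMetricSpec(SelectionSpec.single_atom(296, "CB"),
                                SelectionSpec.single_atom(466, "CB"))
    return StateCriterion("cbeta_distance", metric, cutoff)


def series_from_values(values, dt=1.0):
    return MetricSeries(np.asarray(values, float), dt, "sys", 1, "test")


def state_from_flags(flags, dt=1.0):
    return StateSeries(np.asarray(flags, bool), distance_criterion(), dt,
                       "sys", 1)


class TestClassifyFrames:
    def test_spec_example(self):
        ss = classify_frames(series_from_values([3, 5, 4, 6, 2]),
                             distance_criterion(4.6))
        assert list(ss.active_flags) == [True, False, True, False, True]

    def test_all_above_cutoff(self):
        ss = classify_frames(series_from_values([5, 6, 7]),
                             distance_criterion(4.6))
        assert not ss.active_flags.any()

    def test_tie_is_inactive(self):
        ss = classify_frames(series_from_values([4.6]),
                             distance_criterion(4.6))
        assert not ss.active_flags[0]

    def test_invariant_to_frame_interval(self):
        v = [1.0, 5.0, 2.0]
        a = classify_frames(series_from_values(v, dt=1.0),
                            distance_criterion())
        b = classify_frames(series_from_values(v, dt=10.0),
                            distance_criterion())
        np.testing.assert_array_equal(a.active_flags, b.active_flags)

    @given(st.lists(st.floats(0.0, 10.0), min_size=1, max_size=50),
           st.floats(0.1, 10.0), st.floats(0.1, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_occupancy_monotone_in_cutoff(self, values, c1, c2):
        lo, hi = sorted((c1, c2))
        occ_lo = occupancy(classify_frames(series_from_values(values),
                                           distance_criterion(lo)))
        occ_hi = occupancy(classify_frames(series_from_values(values),
                                           distance_criterion(hi)))
        assert occ_hi >= occ_lo


class TestOccupancy:
    def test_all_active(self):
        assert occupancy(state_from_flags([1, 1, 1])) == 100.0

    def test_three_of_five(self):
        assert occupancy(state_from_flags([1, 0, 1, 0, 1])) == 60.0

    def test_none_active(self):
        assert occupancy(state_from_flags([0, 0])) == 0.0


def brute_force_runs(flags):
    """Independent oracle: scan runs one frame at a time."""
    runs, current = [], 0
    for f in flags:
        if f:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


class TestDwellTimes:
    def test_spec_example(self):
        assert dwell_times(state_from_flags([1, 1, 0, 1, 0])) == [2.0, 1.0]

    def test_all_inactive(self):
        assert dwell_times(state_from_flags([0, 0, 0])) == []

    def test_frame_interval_scales_durations(self):
        assert dwell_times(state_from_flags([1, 1, 0], dt=0.5)) == [1.0]

    def test_against_brute_force_scanner(self, rng):
        flags = rng.random(1000) < 0.3
        ss = state_from_flags(flags, dt=2.0)
        assert dwell_times(ss) == [2.0 * r for r in brute_force_runs(flags)]

    @given(st.lists(st.booleans(), min_size=1, max_size=200),
           st.floats(0.1, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_conservation(self, flags, dt):
        ss = state_from_flags(flags, dt=dt)
        total = sum(dwell_times(ss))
        expected = occupancy(ss) / 100.0 * ss.total_time_ns
        assert total == pytest.approx(expected, abs=1e-9)


class TestReachedActive:
    def test_all_inactive(self):
        assert reached_active(state_from_flags([0, 0])) is False

    def test_single_active_frame(self):
        flags = np.zeros(1000, bool)
        flags[500] = True
        assert reached_active(state_from_flags(flags)) is True

    @given(st.lists(st.booleans(), min_size=1, max_size=100))
    @settings(max_examples=100, deadline=None)
    def test_equals_occupancy_positive(self, flags):
        ss = state_from_flags(flags)
        assert reached_active(ss) == (occupancy(ss) > 0)


class TestReplicaSummary:
    def test_consistency_enforced(self):
        with pytest.raises(ParameterError):
            ReplicaSummary("s", 1, 10.0, False, (1.0,))

    def test_summary_fields(self):
        ss = state_from_flags([1, 1, 0, 1], dt=2.0)
        rep = summarize_replica(ss)
        assert rep.frequency_pct == 75.0
        assert rep.reached_active
        assert rep.dwell_times_ns == (4.0, 2.0)


class TestSkewNormalFit:
    def test_derived_mean_formula_enforced(self):
        with pytest.raises(FitError, match="inconsistent"):
            SkewNormalFit(1.0, 0.5, 2.0, derived_mean=99.0,
                          bin_width_A=0.1, residual_ss=0.0)

    def test_symmetric_input_reduces_to_gaussian(self, rng):
        # alpha is weakly identified near 0 (location/scale absorb small
        # shape); bound both alpha and the skewness it implies
        values = rng.normal(2.0, 0.3, 100_000)
        fit = fit_skew_normal_cutoff(values, 0.1)
        assert abs(fit.shape) < 0.75
        assert abs(sps.skewnorm.stats(fit.shape, moments="s")) < 0.05
        assert fit.derived_mean == pytest.approx(2.0, abs=0.01)

    def test_recovers_known_skew_normal_mean(self):
        values = sps.skewnorm.rvs(4, loc=1.5, scale=0.5, size=100_000,
                                  random_state=7)
        fit = fit_skew_normal_cutoff(values, 0.1)
        closed_form = skew_normal_mean(1.5, 0.5, 4)
        assert closed_form == pytest.approx(
            1.5 + 0.5 * (4 / np.sqrt(17)) * np.sqrt(2 / np.pi)
        )
        assert fit.derived_mean == pytest.approx(closed_form, abs=0.02)

    def test_zero_shape_matches_plain_gaussian_fit(self, rng):
        # alpha = 0 collapses the density to an ordinary Gaussian
        values = rng.normal(2.0, 0.3, 50_000)
        fit = fit_skew_normal_cutoff(values, 0.1)
        from scipy.optimize import curve_fit
        density, edges = np.histogram(values, bins=np.arange(
            values.min(), values.max() + 0.1, 0.1), density=True)
        centres = 0.5 * (edges[:-1] + edges[1:])
        (mu, sigma), _ = curve_fit(
            lambda x, mu, sigma: sps.norm.pdf(x, mu, sigma),
            centres, density, p0=(2.0, 0.3),
        )
        assert fit.derived_mean == pytest.approx(mu, abs=0.01)
        assert fit.scale == pytest.approx(sigma, rel=0.1)

    def test_tight_mode_with_tail_mean_exceeds_mode(self, rng):
        values = np.concatenate([rng.normal(1.7, 0.15, 95_000),
                                 rng.normal(2.4, 0.4, 5_000)])
        fit = fit_skew_normal_cutoff(values, 0.1)
        # the right-hand tail drags the fitted mean above the generating mode
        assert fit.shape > 0
        assert fit.derived_mean > 1.7

    def test_bin_width_stability(self):
        values = sps.skewnorm.rvs(3, loc=1.6, scale=0.4, size=100_000,
                                  random_state=11)
        means = [fit_skew_normal_cutoff(values, bw).derived_mean
                 for bw in (0.05, 0.1, 0.2)]
        assert max(means) - min(means) < 0.02

    def test_too_few_values(self):
        with pytest.raises(FitError, match=">= 100"):
            fit_skew_normal_cutoff(np.ones(50) + np.arange(50) * 0.01)

    def test_degenerate_input(self):
        with pytest.raises(FitError, match="degenerate"):
            fit_skew_normal_cutoff(np.full(200, 2.0))


class TestComputeMetricSeries:
    def _coincident_traj(self, toy_geometry):
        coords = np.repeat(toy_geometry.topology.coords[None], 3, axis=0)
        i = np.nonzero((toy_geometry.topology.residue_numbers == 296)
                       & (toy_geometry.topology.atom_names == "CB"))[0][0]
        j = np.nonzero((toy_geometry.topology.residue_numbers == 466)
                       & (toy_geometry.topology.atom_names == "CB"))[0][0]
        coords[:, j] = coords[:, i]
        return Trajectory(coords, 1.0, "sys", 1), i, j

    def test_coincident_cb_atoms_give_zero(self, toy_geometry):
        traj, _, _ = self._coincident_traj(toy_geometry)
        metric = DistanceMetricSpec(SelectionSpec.single_atom(296, "CB"),
                                    SelectionSpec.single_atom(466, "CB"))
        series = compute_metric_series(traj, toy_geometry.topology, metric,
                                       toy_geometry.reference)
        np.testing.assert_allclose(series.values, [0.0, 0.0, 0.0], atol=1e-12)

    def test_3_4_5_pair(self, toy_geometry):
        traj, i, j = self._coincident_traj(toy_geometry)
        coords = traj.coords.copy()
        coords[:, j] = coords[:, i] + np.array([3.0, 4.0, 0.0])
        traj2 = Trajectory(coords, 1.0, "sys", 1)
        metric = DistanceMetricSpec(SelectionSpec.single_atom(296, "CB"),
                                    SelectionSpec.single_atom(466, "CB"))
        series = compute_metric_series(traj2, toy_geometry.topology, metric,
                                       toy_geometry.reference)
        np.testing.assert_allclose(series.values, 5.0)

    def test_zero_noise_anchor_is_constant(self, toy_geometry):
        from helixstate import SyntheticParams, simulate_state_sequence
        params = SyntheticParams(k_act=1.0, k_deact=0.0, noise_sigma_A=0.0,
                                 n_frames=5, start_state="active", seed=0)
        _, traj = simulate_state_sequence(params, toy_geometry)
        metric = DistanceMetricSpec(SelectionSpec.single_atom(296, "CB"),
                                    SelectionSpec.single_atom(466, "CB"))
        series = compute_metric_series(traj, toy_geometry.topology, metric,
                                       toy_geometry.reference)
        np.testing.assert_allclose(
            series.values, toy_geometry.anchor_distance("active"), atol=1e-9
        )

    def test_rmsd_metric_zero_on_reference_pose(self, toy_geometry):
        coords = np.repeat(toy_geometry.topology.coords[None], 2, axis=0)
        traj = Trajectory(coords, 1.0, "sys", 1)
        metric = RmsdMetricSpec(fit=SelectionSpec((248, 459), {"CA"}),
                                calc=SelectionSpec((466, 473), {"CA"}))
        series = compute_metric_series(traj, toy_geometry.topology, metric,
                                       toy_geometry.reference)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)


class TestSeriesExport:
    def test_tsv_shape_and_header(self):
        metric = series_from_values([1.0, 5.0])
        state = classify_frames(metric, distance_criterion())
        text = series_to_tsv(metric, state)
        lines = text.strip().split("\n")
        assert lines[0] == "frame\ttime_ns\tvalue_A\tactive"
        assert len(lines) == 3
        assert lines[1].split("\t") == ["0", "0.000", "1.0000", "1"]
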