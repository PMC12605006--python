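"""Per-frame metrics -> state classification, occupancy, dwell times, cutoffs.

Two geometric criteria define the "active" state of the mobile helix:

* ``cbeta_distance`` — distance between two named side-chain anchor atoms
  (reference cutoff 4.6 A, measured in the agonist-bound crystal structure);
* ``h12_rmsd`` — RMSD of the mobile helix residues to their reference pose
  after superposing on the rigid core (cutoff 1.9 A, derived as the mean of a
  skew-normal fitted to the pooled RMSD histogram of the always-active system).

A frame is active iff its metric is strictly below the cutoff; ties count as
inactive so classification is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import FitError, ParameterError
from .geometry import pair_distance, rmsd_after_fit_many
from .structure_io import SelectionSpec, StructureModel, Trajectory, select_atoms

__all__ = [
    "DistanceMetricSpec",
    "RmsdMetricSpec",
    "StateCriterion",
    "MetricSeries",
    "StateSeries",
    "SkewNormalFit",
    "ReplicaSummary",
    "compute_metric_series",
    "fit_skew_normal_cutoff",
    "classify_frames",
    "occupancy",
    "dwell_times",
    "reached_active",
    "summarize_replica",
    "series_to_tsv",
]


@dataclass(frozen=True)
class DistanceMetricSpec:
    """Pair distance between two single-atom selections (e.g. two C-beta)."""

    atom_a: SelectionSpec
    atom_b: SelectionSpec
    kind: str = "cbeta_distance"


@dataclass(frozen=True)
class RmsdMetricSpec:
    """RMSD of ``calc`` atoms to the reference after fitting on ``fit`` atoms."""

    fit: SelectionSpec
    calc: SelectionSpec
    kind: str = "h12_rmsd"


@dataclass(frozen=True)
class StateCriterion:
    name: str
    metric: DistanceMetricSpec | RmsdMetricSpec
    cutoff_A: float
    active_direction: str = "below"

    def __post_init__(self) -> None:
        if not self.cutoff_A > 0:
            raise ParameterError(f"cutoff must be > 0 A, got {self.cutoff_A}")
        if self.active_direction != "below":
            raise ParameterError(
                "only active_direction='below' is supported"
            )


@dataclass
class MetricSeries:
    """One metric value (Angstrom) per frame of one replica."""

    values: np.ndarray
    frame_interval_ns: float
    system_label: str = ""
    replica_index: int = 1
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ParameterError("metric series must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ParameterError("metric values must be finite and >= 0")
        if not self.frame_interval_ns > 0:
            raise ParameterError("frame_interval_ns must be > 0")

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def total_time_ns(self) -> float:
        return self.n_frames * self.frame_interval_ns


@dataclass
class StateSeries:
    """Boolean active/inactive flags per frame, tied to the criterion used."""

    active_flags: np.ndarray
    criterion: StateCriterion
    frame_interval_ns: float
    system_label: str = ""
    replica_index: int = 1

    def __post_init__(self) -> None:
        self.active_flags = np.asarray(self.active_flags, dtype=bool)
        if self.active_flags.ndim != 1 or self.active_flags.size < 1:
            raise ParameterError("state series must be a non-empty 1-D array")
        if not self.frame_interval_ns > 0:
            raise ParameterError("frame_interval_ns must be > 0")

    @property
    def n_frames(self) -> int:
        return self.active_flags.size

    @property
    def total_time_ns(self) -> float:
        return self.n_frames * self.frame_interval_ns


@dataclass(frozen=True)
class SkewNormalFit:
    """Least-squares skew-normal fit to a metric histogram.

    The distribution mean follows the closed form
    ``mean = xi + omega * delta * sqrt(2/pi)`` with
    ``delta = alpha / sqrt(1 + alpha^2)``.
    """

    location: float   # xi
    scale: float      # omega
    shape: float      # alpha
    derived_mean: float
    bin_width_A: float
    residual_ss: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise FitError(f"skew-normal scale must be > 0, got {self.scale}")
        expected = skew_normal_mean(self.location, self.scale, self.shape)
        if abs(self.derived_mean - expected) > 1e-9:
            raise FitError(
                f"derived_mean {self.derived_mean} inconsistent with "
                f"parameters (closed form {expected})"
            )


@dataclass(frozen=True)
class ReplicaSummary:
    system_label: str
    replica_index: int
    frequency_pct: float
    reached_active: bool
    dwell_times_ns: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency_pct <= 100.0:
            raise ParameterError(
                f"frequency_pct out of [0, 100]: {self.frequency_pct}"
            )
        if self.reached_active != (self.frequency_pct > 0):
            raise ParameterError(
                "reached_active must equal (frequency_pct > 0)"
            )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _single_index(model: StructureModel, spec: SelectionSpec) -> int:
    idx = select_atoms(model, spec)
    if idx.size != 1:
        raise ParameterError(
            f"distance metric needs single-atom selections, got {idx.size} "
            f"atoms for {spec}"
        )
    return int(idx[0])


def compute_metric_series(traj: Trajectory, topology: StructureModel,
                          metric: DistanceMetricSpec | RmsdMetricSpec,
                          reference: StructureModel) -> MetricSeries:
    """Evaluate a geometric metric for every frame of a trajectory.

    Selections are resolved on the topology (frames share its atom order) and,
    for the RMSD metric, independently on the reference model, which may carry
    a different atom order.
    """
    if isinstance(metric, DistanceMetricSpec):
        i = _single_index(topology, metric.atom_a)
        j = _single_index(topology, metric.atom_b)
        values = np.linalg.norm(traj.coords[:, i, :] - traj.coords[:, j, :],
                                axis=1)
    elif isinstance(metric, RmsdMetricSpec):
        fit_idx = select_atoms(topology, metric.fit)
        calc_idx = select_atoms(topology, metric.calc)
        ref_fit = select_atoms(reference, metric.fit)
        ref_calc = select_atoms(reference, metric.calc)
        if ref_fit.size != fit_idx.size or ref_calc.size != calc_idx.size:
            raise ParameterError(
                "fit/calc selections resolve to different atom counts on "
                "topology and reference"
            )
        # re-index reference coordinates into topology atom order
        ref_coords = np.zeros((topology.n_atoms, 3), dtype=float)
        ref_coords[fit_idx] = reference.coords[ref_fit]
        ref_coords[calc_idx] = reference.coords[ref_calc]
        values = rmsd_after_fit_many(traj.coords, ref_coords, fit_idx, calc_idx)
    else:
        raise ParameterError(f"unknown metric spec {type(metric).__name__}")
    return MetricSeries(values, traj.frame_interval_ns, traj.system_label,
                        traj.replica_index, metric.kind)


# ---------------------------------------------------------------------------
# Skew-normal cutoff
# ---------------------------------------------------------------------------

def skew_normal_mean(location: float, scale: float, shape: float) -> float:
    """Closed-form mean xi + omega * delta * sqrt(2/pi)."""
    delta = shape / math.sqrt(1.0 + shape * shape)
    return location + scale * delta * math.sqrt(2.0 / math.pi)


def fit_skew_normal_cutoff(values: Sequence[float] | np.ndarray,
                           bin_width_A: float = 0.1) -> SkewNormalFit:
    """Fit a skew-normal density to the normalised histogram of pooled values.

    The fit is least squares on (bin centre, density) pairs; the returned
    ``derived_mean`` — the fitted distribution's mean — is the quantity used
    as a state cutoff downstream.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 100:
        raise FitError(f"need >= 100 values to fit, got {values.size}")
    if not bin_width_A > 0:
        raise FitError(f"bin width must be > 0, got {bin_width_A}")
    vmin, vmax = values.min(), values.max()
    if vmax - vmin < 1e-12:
        raise FitError("degenerate (single-valued) input")
    edges = np.arange(vmin, vmax + bin_width_A, bin_width_A)
    if edges.size < 4:
        raise FitError(
            f"bin width {bin_width_A} A leaves fewer than 3 bins over the "
            f"data range [{vmin:.3g}, {vmax:.3g}]"
        )
    density, edges = np.histogram(values, bins=edges, density=True)
    centres = 0.5 * (edges[:-1] + edges[1:])

    def pdf(x, shape, loc, scale):
        return stats.skewnorm.pdf(x, shape, loc=loc, scale=scale)

    p0 = (0.0, float(np.mean(values)), float(np.std(values)))
    try:
        popt, _ = optimize.curve_fit(
            pdf, centres, density, p0=p0,
            bounds=([-50.0, vmin - 10.0, 1e-6],
                    [50.0, vmax + 10.0, (vmax - vmin) * 10.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"skew-normal fit did not converge: {exc}") from exc
    shape, loc, scale = (float(p) for p in popt)
    residual_ss = float(np.sum((pdf(centres, shape, loc, scale) - density) ** 2))
    return SkewNormalFit(
        location=loc, scale=scale, shape=shape,
        derived_mean=skew_normal_mean(loc, scale, shape),
        bin_width_A=float(bin_width_A), residual_ss=residual_ss,
    )


# ---------------------------------------------------------------------------
# Classification and per-replica statistics
# ---------------------------------------------------------------------------

def classify_frames(series: MetricSeries,
                    criterion: StateCriterion) -> StateSeries:
    """Flag each frame active iff metric < cutoff (strict; ties inactive)."""
    flags = series.values < criterion.cutoff_A
    return StateSeries(flags, criterion, series.frame_interval_ns,
                       series.system_label, series.replica_index)


def occupancy(series: StateSeries) -> float:
    """Percentage of frames classified active, in [0, 100]."""
    return 100.0 * float(np.count_nonzero(series.active_flags)) / series.n_frames


def dwell_times(series: StateSeries) -> list[float]:
    """Durations (ns) of maximal consecutive active runs, in trajectory order."""
    flags = series.active_flags
    padded = np.concatenate(([False], flags, [False])).astype(int)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return [(e - s) * series.frame_interval_ns for s, e in zip(starts, ends)]


def reached_active(series: StateSeries) -> bool:
    """Whether the replica was active in at least one frame."""
    return bool(series.active_flags.any())


def summarize_replica(series: StateSeries) -> ReplicaSummary:
    return ReplicaSummary(
        system_label=series.system_label,
        replica_index=series.replica_index,
        frequency_pct=occupancy(series),
        reached_active=reached_active(series),
        dwell_times_ns=tuple(dwell_times(series)),
    )


def series_to_tsv(metric: MetricSeries, state: StateSeries) -> str:
    """Render per-frame values as TSV: frame, time_ns, value_A, active."""
    if state.n_frames != metric.n_frames:
        raise ParameterError("metric and state series lengths differ")
    lines = ["frame\ttime_ns\tvalue_A\tactive"]
    dt = metric.frame_interval_ns
    for f, (v, a) in enumerate(zip(metric.values, state.active_flags)):
        lines.append(f"{f}\t{f * dt:.3f}\t{v:.4f}\t{int(a)}")
    return "\n".join(lines) + "\n"
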