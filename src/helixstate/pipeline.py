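"""Config-driven orchestration: trajectories in, report bundle out.

``run_analysis`` reads a validated :class:`AnalysisConfig`, evaluates both
state criteria for every replica of every system, and writes a deterministic
report bundle: pooled metric histograms, per-replica summaries, per-system
summaries, pairwise test results with significance stars, and a compact
reached-state table.  Percentages are printed with 2 decimals and p-values
with 3, matching the granularity of the published tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .errors import ConfigError
from .replica_stats import (
    SystemSummary,
    compare_systems,
    summarize_system,
)
from .state_model import (
    DistanceMetricSpec,
    MetricSeries,
    RmsdMetricSpec,
    StateCriterion,
    StateSeries,
    classify_frames,
    fit_skew_normal_cutoff,
    compute_metric_series,
    summarize_replica,
)
from .structure_io import (
    SelectionSpec,
    StructureModel,
    read_pdb,
    read_traj,
)

__all__ = ["AnalysisConfig", "SystemSpec", "run_analysis", "load_config"]

CRITERIA = ("distance", "rmsd")


@dataclass(frozen=True)
class SystemSpec:
    label: str
    trajectories: tuple[str, ...]
    replica_indices: tuple[int, ...]


@dataclass(frozen=True)
class AnalysisConfig:
    reference_pdb: Path
    topology_pdb: Path
    systems: tuple[SystemSpec, ...]
    frame_interval_ns: float = 1.0
    histogram_bin_width_A: float = 0.1
    output_dir: Path = Path("analysis")
    comparisons: tuple[tuple[str, str], ...] = ()
    mw_continuity: bool = True
    # distance criterion
    distance_res_a: int = 296
    distance_res_b: int = 466
    distance_atom: str = "CB"
    distance_cutoff_A: float = 4.6
    # RMSD criterion
    rmsd_calc_residues: tuple[int, int] = (466, 473)
    rmsd_fit_residues: tuple[int, int] = (248, 459)
    rmsd_atom: str = "CA"
    rmsd_cutoff_A: float | None = 1.9
    rmsd_fit_from: str | None = None

    def validate(self) -> None:
        for path, what in ((self.reference_pdb, "reference_pdb"),
                           (self.topology_pdb, "topology_pdb")):
            if not Path(path).exists():
                raise ConfigError(f"{what} does not exist: {path}")
        if not self.systems:
            raise ConfigError("no systems configured")
        labels = [s.label for s in self.systems]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"duplicate system labels: {labels}")
        for system in self.systems:
            if not system.trajectories:
                raise ConfigError(f"system '{system.label}' has no trajectories")
            for t in system.trajectories:
                if not Path(t).exists():
                    raise ConfigError(
                        f"trajectory for '{system.label}' does not exist: {t}"
                    )
        if not self.frame_interval_ns > 0:
            raise ConfigError("frame_interval_ns must be > 0")
        if not self.histogram_bin_width_A > 0:
            raise ConfigError("histogram_bin_width_A must be > 0")
        if not self.distance_cutoff_A > 0:
            raise ConfigError("distance cutoff must be > 0")
        if self.rmsd_fit_from is None:
            if self.rmsd_cutoff_A is None or not self.rmsd_cutoff_A > 0:
                raise ConfigError(
                    "rmsd criterion needs a positive cutoff_A or fit_from"
                )
        elif self.rmsd_fit_from not in labels:
            raise ConfigError(
                f"rmsd fit_from '{self.rmsd_fit_from}' is not a configured "
                f"system (have {labels})"
            )
        for a, b in self.comparisons:
            for lab in (a, b):
                if lab not in labels:
                    raise ConfigError(
                        f"comparison references unknown system '{lab}'"
                    )

    def distance_metric(self) -> DistanceMetricSpec:
        return DistanceMetricSpec(
            SelectionSpec.single_atom(self.distance_res_a, self.distance_atom),
            SelectionSpec.single_atom(self.distance_res_b, self.distance_atom),
        )

    def rmsd_metric(self) -> RmsdMetricSpec:
        return RmsdMetricSpec(
            fit=SelectionSpec(tuple(self.rmsd_fit_residues),
                              frozenset({self.rmsd_atom})),
            calc=SelectionSpec(tuple(self.rmsd_calc_residues),
                               frozenset({self.rmsd_atom})),
        )


def load_config(path: str | Path) -> AnalysisConfig:
    """Load and validate a YAML analysis configuration.

    Relative paths inside the file resolve against the file's directory.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file does not exist: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping: {path}")
    base = path.parent

    def respath(p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    try:
        systems = []
        for entry in raw.get("systems", []):
            trajs = tuple(str(respath(t)) for t in entry["trajectories"])
            indices = tuple(
                entry.get("replica_indices", range(1, len(trajs) + 1))
            )
            if len(indices) != len(trajs):
                raise ConfigError(
                    f"system '{entry['label']}': {len(indices)} replica "
                    f"indices for {len(trajs)} trajectories"
                )
            systems.append(SystemSpec(str(entry["label"]), trajs, indices))
        criteria = raw.get("criteria", {})
        dist = criteria.get("distance", {})
        rmsd = criteria.get("rmsd", {})
        config = AnalysisConfig(
            reference_pdb=respath(raw["reference_pdb"]),
            topology_pdb=respath(raw.get("topology_pdb",
                                         raw["reference_pdb"])),
            systems=tuple(systems),
            frame_interval_ns=float(raw.get("frame_interval_ns", 1.0)),
            histogram_bin_width_A=float(raw.get("histogram_bin_width_A", 0.1)),
            output_dir=respath(str(raw.get("output_dir", "analysis"))),
            comparisons=tuple(
                (str(a), str(b)) for a, b in raw.get("comparisons", [])
            ),
            mw_continuity=bool(raw.get("mw_continuity", True)),
            distance_res_a=int(dist.get("res_a", 296)),
            distance_res_b=int(dist.get("res_b", 466)),
            distance_atom=str(dist.get("atom", "CB")),
            distance_cutoff_A=float(dist.get("cutoff_A", 4.6)),
            rmsd_calc_residues=tuple(rmsd.get("calc_residues", (466, 473))),
            rmsd_fit_residues=tuple(rmsd.get("fit_residues", (248, 459))),
            rmsd_atom=str(rmsd.get("atom", "CA")),
            rmsd_cutoff_A=(None if "fit_from" in rmsd
                           else float(rmsd.get("cutoff_A", 1.9))),
            rmsd_fit_from=rmsd.get("fit_from"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
    config.validate()
    return config


def _histogram_tsv(values: np.ndarray, bin_width: float) -> str:
    vmin, vmax = float(values.min()), float(values.max())
    edges = np.arange(vmin, vmax + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([vmin, vmin + bin_width])
    counts, edges = np.histogram(values, bins=edges)
    total = counts.sum()
    lines = ["bin_left_A\tbin_right_A\tcount\tdensity"]
    for left, right, c in zip(edges[:-1], edges[1:], counts):
        dens = c / (total * bin_width) if total else 0.0
        lines.append(f"{left:.4f}\t{right:.4f}\t{c}\t{dens:.6f}")
    return "\n".join(lines) + "\n"


def run_analysis(config: AnalysisConfig) -> dict[str, Any]:
    """Execute the full analysis and write the report bundle.

    Returns the machine-readable report (also written as ``summary.json``).
    The analysis path contains no randomness: re-running on identical inputs
    reproduces the bundle byte for byte.
    """
    config.validate()
    topology = _single_model(read_pdb(config.topology_pdb), "topology")
    reference = _single_model(read_pdb(config.reference_pdb), "reference")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    metrics = {"distance": config.distance_metric(),
               "rmsd": config.rmsd_metric()}
    # metric series for every system x replica x criterion
    series: dict[str, dict[str, list[MetricSeries]]] = {
        c: {s.label: [] for s in config.systems} for c in CRITERIA
    }
    for system in config.systems:
        for path, replica in zip(system.trajectories, system.replica_indices):
            traj = read_traj(path, topology, config.frame_interval_ns,
                             system.label, replica)
            for crit in CRITERIA:
                series[crit][system.label].append(
                    compute_metric_series(traj, topology, metrics[crit],
                                          reference)
                )

    cutoffs = {"distance": config.distance_cutoff_A,
               "rmsd": config.rmsd_cutoff_A}
    fit_report = None
    if config.rmsd_fit_from is not None:
        pooled = np.concatenate(
            [m.values for m in series["rmsd"][config.rmsd_fit_from]]
        )
        fit = fit_skew_normal_cutoff(pooled, config.histogram_bin_width_A)
        cutoffs["rmsd"] = fit.derived_mean
        fit_report = {
            "fitted_from": config.rmsd_fit_from,
            "location": fit.location, "scale": fit.scale,
            "shape": fit.shape, "derived_mean": fit.derived_mean,
            "residual_ss": fit.residual_ss,
        }

    criteria = {
        "distance": StateCriterion("cbeta_distance", metrics["distance"],
                                   cutoffs["distance"]),
        "rmsd": StateCriterion("h12_rmsd", metrics["rmsd"], cutoffs["rmsd"]),
    }

    state_series: dict[str, dict[str, list[StateSeries]]] = {
        c: {s.label: [] for s in config.systems} for c in CRITERIA
    }
    summaries: dict[str, dict[str, SystemSummary]] = {c: {} for c in CRITERIA}
    replica_rows = ["system\tcriterion\treplica\tfrequency_pct\treached"
                    "\tn_dwells\ttotal_dwell_ns\tlongest_dwell_ns"]
    system_rows = ["system\tcriterion\tn_replicas\tmean_frequency_pct"
                   "\tpooled_frequency_pct\tn_reached"]
    for crit in CRITERIA:
        for system in config.systems:
            label = system.label
            ss_list = [classify_frames(m, criteria[crit])
                       for m in series[crit][label]]
            state_series[crit][label] = ss_list
            summaries[crit][label] = summarize_system(ss_list)
            pooled_vals = np.concatenate(
                [m.values for m in series[crit][label]]
            )
            (out / f"hist_{label}_{crit}.tsv").write_text(
                _histogram_tsv(pooled_vals, config.histogram_bin_width_A)
            )
            pooled_pct = 100.0 * sum(
                int(np.count_nonzero(s.active_flags)) for s in ss_list
            ) / sum(s.n_frames for s in ss_list)
            summary = summaries[crit][label]
            system_rows.append(
                f"{label}\t{crit}\t{summary.n_replicas}"
                f"\t{summary.mean_frequency_pct:.2f}\t{pooled_pct:.2f}"
                f"\t{summary.n_reached}"
            )
            for s in ss_list:
                rep = summarize_replica(s)
                dwells = rep.dwell_times_ns
                replica_rows.append(
                    f"{label}\t{crit}\t{rep.replica_index}"
                    f"\t{rep.frequency_pct:.2f}\t{int(rep.reached_active)}"
                    f"\t{len(dwells)}\t{sum(dwells):.2f}"
                    f"\t{max(dwells) if dwells else 0.0:.2f}"
                )
    (out / "replica_summary.tsv").write_text("\n".join(replica_rows) + "\n")
    (out / "system_summary.tsv").write_text("\n".join(system_rows) + "\n")

    comparison_rows = ["pair\tcriterion\ttest\tsidedness\tstatistic"
                       "\tp_value\tstars"]
    comparison_records: list[dict[str, Any]] = []
    for a, b in config.comparisons:
        for crit in CRITERIA:
            for result in compare_systems(summaries[crit][a],
                                          summaries[crit][b],
                                          use_continuity=config.mw_continuity):
                comparison_rows.append(
                    f"{a}_vs_{b}\t{crit}\t{result.test_name}"
                    f"\t{result.sidedness}\t{result.statistic:.4f}"
                    f"\t{result.p_value:.3f}\t{result.stars}"
                )
                comparison_records.append({
                    "pair": [a, b], "criterion": crit,
                    "test": result.test_name,
                    "sidedness": result.sidedness,
                    "statistic": result.statistic,
                    "p_value": result.p_value,
                    "stars": result.stars,
                })
    (out / "comparisons.tsv").write_text("\n".join(comparison_rows) + "\n")

    table_rows = ["row\tdistance\trmsd"]
    for system in config.systems:
        cells = [f"{summaries[c][system.label].n_reached} out of "
                 f"{summaries[c][system.label].n_replicas} runs"
                 for c in CRITERIA]
        table_rows.append(
            f"{system.label} reaching active state\t" + "\t".join(cells)
        )
    for a, b in config.comparisons:
        cells = []
        for crit in CRITERIA:
            tt = [r for r in comparison_records
                  if r["pair"] == [a, b] and r["criterion"] == crit
                  and r["test"] == "student_t_pooled"][0]
            cells.append(f"{tt['stars']} (p = {tt['p_value']:.3f})")
        table_rows.append(f"Significance {a} vs {b}\t" + "\t".join(cells))
    (out / "reached_state_table.tsv").write_text("\n".join(table_rows) + "\n")

    report: dict[str, Any] = {
        "cutoffs_A": {c: float(cutoffs[c]) for c in CRITERIA},
        "rmsd_cutoff_fit": fit_report,
        "systems": {
            s.label: {
                crit: {
                    "n_replicas": summaries[crit][s.label].n_replicas,
                    "frequencies_pct": list(
                        summaries[crit][s.label].frequencies_pct
                    ),
                    "mean_frequency_pct":
                        summaries[crit][s.label].mean_frequency_pct,
                    "n_reached": summaries[crit][s.label].n_reached,
                } for crit in CRITERIA
            } for s in config.systems
        },
        "comparisons": comparison_records,
        "outputs": sorted(
            {p.name for p in out.iterdir() if p.is_file()}
            | {"summary.json"}
        ),
    }
    (out / "summary.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report


def _single_model(models, what: str) -> StructureModel:
    if isinstance(models, list):
        raise ConfigError(f"{what} PDB must contain exactly one model")
    return models
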