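"""Desk-scale surrogate trajectories with a known two-state ground truth.

A rigid toy scaffold (C-alpha pseudo-atoms for residues 248-465 plus the
C-beta of residue 296) carries a mobile 9-atom helix segment (C-alpha of
residues 466-473 plus the C-beta of 466).  The segment jumps between an
"active" anchor pose — anchor-atom distance below the 4.6 A reference and
zero RMSD to the reference — and an "inactive" anchor pose far outside both
criteria, following a discrete-time embedding of a two-state telegraph
process.  Isotropic Gaussian noise is added to every atom every frame.  The
ground-truth state sequence is retained so classification can be scored
exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .structure_io import (
    Atom,
    StructureModel,
    Trajectory,
    write_pdb,
    write_xyz_traj,
)

__all__ = [
    "ToyGeometry",
    "SyntheticParams",
    "make_toy_geometry",
    "simulate_states",
    "simulate_state_sequence",
    "generate_cohort",
    "paper_like_systems",
    "stationary_p_active",
]

_CORE_FIRST, _CORE_LAST = 248, 465     # rigid scaffold residues
_HELIX_FIRST, _HELIX_LAST = 466, 473   # mobile segment residues
_ANCHOR_RES_A, _ANCHOR_RES_B = 296, 466  # C-beta anchor pair

_DISTANCE_CUTOFF_A = 4.6
_RMSD_CUTOFF_A = 1.9
_INACTIVE_MIN_DISTANCE_A = 45.0


@dataclass(frozen=True)
class ToyGeometry:
    """Rigid scaffold plus anchor poses for the mobile helix segment."""

    topology: StructureModel          # scaffold with helix in the active pose
    mobile_indices: np.ndarray        # atom indices of the mobile segment
    anchors: dict[str, np.ndarray]    # pose name -> (n_mobile, 3) coordinates

    def __post_init__(self) -> None:
        d_active = self.anchor_distance("active")
        d_inactive = self.anchor_distance("inactive")
        if not d_active < _DISTANCE_CUTOFF_A:
            raise ParameterError(
                f"active anchor distance {d_active:.2f} A not below the "
                f"{_DISTANCE_CUTOFF_A} A cutoff"
            )
        if not d_inactive > _INACTIVE_MIN_DISTANCE_A:
            raise ParameterError(
                f"inactive anchor distance {d_inactive:.2f} A not beyond "
                f"{_INACTIVE_MIN_DISTANCE_A} A"
            )
        rmsd_gap = self.anchor_rmsd_gap()
        if not rmsd_gap >= 10.0 * _RMSD_CUTOFF_A:
            raise ParameterError(
                f"anchor RMSD separation {rmsd_gap:.2f} A is below 10x the "
                f"{_RMSD_CUTOFF_A} A cutoff"
            )

    @property
    def reference(self) -> StructureModel:
        """Reference model: the scaffold with the helix in the active pose."""
        return self.topology

    def _anchor_atom_index(self, residue: int) -> int:
        mask = (self.topology.residue_numbers == residue) \
            & (self.topology.atom_names == "CB")
        return int(np.nonzero(mask)[0][0])

    def anchor_distance(self, pose: str) -> float:
        """Anchor-pair C-beta distance with the helix in the given pose."""
        coords = self.pose_coords(pose)
        i = self._anchor_atom_index(_ANCHOR_RES_A)
        j = self._anchor_atom_index(_ANCHOR_RES_B)
        return float(np.linalg.norm(coords[i] - coords[j]))

    def anchor_rmsd_gap(self) -> float:
        diff = self.anchors["active"] - self.anchors["inactive"]
        return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))

    def pose_coords(self, pose: str) -> np.ndarray:
        """Full-topology coordinates with the mobile segment at a named pose."""
        if pose not in self.anchors:
            raise ParameterError(
                f"unknown pose '{pose}'; have {sorted(self.anchors)}"
            )
        coords = self.topology.coords.copy()
        coords[self.mobile_indices] = self.anchors[pose]
        return coords


def _alpha_helix(n: int, radius: float = 2.3, rise: float = 1.5,
                 turn_deg: float = 100.0) -> np.ndarray:
    i = np.arange(n)
    ang = np.deg2rad(turn_deg) * i
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            rise * i])


def make_toy_geometry(active_distance_A: float = 3.5,
                      inactive_shift_A: float = 55.0,
                      near_active_distance_A: float = 6.6) -> ToyGeometry:
    """Build the deterministic toy scaffold and its three anchor poses.

    ``active_distance_A`` defaults to 3.5 A so the active pose sits ~4 noise
    standard deviations below the 4.6 A cutoff at the default 0.2 A noise
    (the pair distance fluctuates with sd sqrt(2) x sigma).  The
    "near_active" pose reproduces an almost-docked helix whose anchor
    distance (default 6.6 A) stays above the cutoff.
    """
    if not 0 < active_distance_A < _DISTANCE_CUTOFF_A:
        raise ParameterError(
            f"active_distance_A must lie in (0, {_DISTANCE_CUTOFF_A}), "
            f"got {active_distance_A}"
        )
    atoms: list[Atom] = []
    # coarse rigid scaffold: one CA per residue on a wide helical curve
    n_core = _CORE_LAST - _CORE_FIRST + 1
    core_ca = np.column_stack([
        8.0 * np.cos(np.deg2rad(100.0) * np.arange(n_core)),
        8.0 * np.sin(np.deg2rad(100.0) * np.arange(n_core)),
        0.5 * np.arange(n_core),
    ])
    cb_296 = None
    outward = None
    for k, res in enumerate(range(_CORE_FIRST, _CORE_LAST + 1)):
        name = "THR" if res in (_ANCHOR_RES_A, _ANCHOR_RES_B) else "ALA"
        atoms.append(Atom("A", res, name, "CA", "C", core_ca[k]))
        if res == _ANCHOR_RES_A:
            ang = np.deg2rad(100.0) * k
            outward = np.array([np.cos(ang), np.sin(ang), 0.0])
            cb_296 = core_ca[k] + 1.5 * outward
            atoms.append(Atom("A", res, name, "CB", "C", cb_296))
    assert cb_296 is not None and outward is not None

    # mobile segment in local coordinates: CA 466-473 on an ideal helix,
    # CB of 466 offset radially from its CA
    seg_ca = _alpha_helix(_HELIX_LAST - _HELIX_FIRST + 1)
    seg_cb466 = seg_ca[0] + np.array([1.5, 0.0, 0.0])
    # place the segment so CB(466) sits at the requested anchor distance
    shift = cb_296 + active_distance_A * outward - seg_cb466
    seg_ca = seg_ca + shift
    seg_cb466 = seg_cb466 + shift

    mobile_atoms: list[Atom] = []
    for k, res in enumerate(range(_HELIX_FIRST, _HELIX_LAST + 1)):
        name = "THR" if res == _ANCHOR_RES_B else "ALA"
        mobile_atoms.append(Atom("A", res, name, "CA", "C", seg_ca[k]))
        if res == _ANCHOR_RES_B:
            mobile_atoms.append(Atom("A", res, name, "CB", "C", seg_cb466))
    atoms.extend(mobile_atoms)
    topology = StructureModel.from_atoms(atoms)
    mobile_indices = np.nonzero(topology.residue_numbers >= _HELIX_FIRST)[0]

    active = topology.coords[mobile_indices].copy()
    anchors = {
        "active": active,
        "inactive": active + inactive_shift_A * outward,
        "near_active": active
        + (near_active_distance_A - active_distance_A) * outward,
    }
    return ToyGeometry(topology, mobile_indices, anchors)


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of one synthetic replica.

    Rates are in transitions/ns; with both rates positive the stationary
    active probability is ``k_act / (k_act + k_deact)``.  ``start_state`` may
    be "active", "inactive", or "stationary" (drawn from the stationary
    distribution).  ``active_pose`` selects which anchor represents the
    active-side state ("active" or "near_active" for variant-like cohorts).
    """

    k_act: float
    k_deact: float
    noise_sigma_A: float = 0.2
    n_frames: int = 1000
    frame_interval_ns: float = 1.0
    start_state: str = "inactive"
    seed: int = 0
    active_pose: str = "active"

    def __post_init__(self) -> None:
        if self.k_act < 0 or self.k_deact < 0:
            raise ParameterError("rates must be >= 0")
        if self.noise_sigma_A < 0:
            raise ParameterError("noise sigma must be >= 0")
        if self.n_frames < 1:
            raise ParameterError("need >= 1 frame")
        if not self.frame_interval_ns > 0:
            raise ParameterError("frame_interval_ns must be > 0")
        if self.start_state not in ("active", "inactive", "stationary"):
            raise ParameterError(f"bad start_state '{self.start_state}'")
        if self.start_state == "stationary" and self.k_act + self.k_deact == 0:
            raise ParameterError(
                "stationary start undefined when both rates are zero"
            )
        if self.active_pose not in ("active", "near_active"):
            raise ParameterError(f"bad active_pose '{self.active_pose}'")


def stationary_p_active(params: SyntheticParams) -> float:
    """Stationary active probability k_act / (k_act + k_deact)."""
    total = params.k_act + params.k_deact
    if total == 0:
        raise ParameterError("both rates zero: no stationary distribution")
    return params.k_act / total


def simulate_states(params: SyntheticParams,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate only the ground-truth boolean state sequence.

    Discrete-time embedding of the telegraph process: per frame the switch
    probability is ``1 - exp(-k dt)`` for the rate leaving the current state.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    dt = params.frame_interval_ns
    p_on = 1.0 - math.exp(-params.k_act * dt)
    p_off = 1.0 - math.exp(-params.k_deact * dt)
    states = np.empty(params.n_frames, dtype=bool)
    if params.start_state == "stationary":
        states[0] = rng.random() < stationary_p_active(params)
    else:
        states[0] = params.start_state == "active"
    draws = rng.random(params.n_frames - 1)
    for t in range(1, params.n_frames):
        if states[t - 1]:
            states[t] = draws[t - 1] >= p_off
        else:
            states[t] = draws[t - 1] < p_on
    return states


def simulate_state_sequence(
    params: SyntheticParams,
    geometry: ToyGeometry | None = None,
    system_label: str = "",
    replica_index: int = 1,
) -> tuple[np.ndarray, Trajectory]:
    """Simulate one replica; returns (ground-truth states, trajectory).

    Frame coordinates are the current state's anchor pose (scaffold fixed)
    plus i.i.d. Gaussian noise on every coordinate of every atom.
    """
    if geometry is None:
        geometry = make_toy_geometry()
    rng = np.random.default_rng(params.seed)
    states = simulate_states(params, rng)
    base_active = geometry.pose_coords(params.active_pose)
    base_inactive = geometry.pose_coords("inactive")
    coords = np.where(states[:, None, None], base_active, base_inactive)
    if params.noise_sigma_A > 0:
        coords = coords + rng.normal(0.0, params.noise_sigma_A, coords.shape)
    traj = Trajectory(coords, params.frame_interval_ns, system_label,
                      replica_index)
    return states, traj


def _replica_seed(base_seed: int, label: str, replica: int) -> int:
    ss = np.random.SeedSequence(
        entropy=[int(base_seed), zlib.crc32(label.encode()), int(replica)]
    )
    return int(ss.generate_state(1, np.uint64)[0])


def paper_like_systems(seed: int = 0, n_frames: int = 1000,
                       noise_sigma_A: float = 0.2,
                       frame_interval_ns: float = 1.0,
                       ) -> list[tuple[str, SyntheticParams]]:
    """Four-system preset mirroring the active/inactive x WT/variant layout.

    Rates are chosen so the cohorts qualitatively reproduce the published
    behaviour pattern: high occupancy for active WT, near-zero for the
    variant started active (its helix only reaches an almost-docked pose),
    a minority of inactive-WT replicas transitioning with long persistence,
    and rare transitions for the variant started inactive.
    """
    common = dict(noise_sigma_A=noise_sigma_A, n_frames=n_frames,
                  frame_interval_ns=frame_interval_ns, seed=seed)
    return [
        ("active_WT", SyntheticParams(k_act=0.010, k_deact=0.027,
                                      start_state="active", **common)),
        ("active_T296I", SyntheticParams(k_act=0.010, k_deact=0.027,
                                         start_state="active",
                                         active_pose="near_active", **common)),
        ("inactive_WT", SyntheticParams(k_act=5.1e-4, k_deact=0.002,
                                        start_state="inactive", **common)),
        ("inactive_T296I", SyntheticParams(k_act=6.9e-5, k_deact=0.002,
                                           start_state="inactive", **common)),
    ]


def generate_cohort(systems: Sequence[tuple[str, SyntheticParams]],
                    out_dir: str | Path, n_replicas: int = 15,
                    geometry: ToyGeometry | None = None) -> dict:
    """Write a full synthetic cohort to disk; returns the manifest.

    Layout: ``topology.pdb``, ``reference.pdb``, one XYZ stream per replica
    under ``<label>/``, a pooled ground-truth TSV, a ready-to-run analysis
    config stub (YAML), and a JSON manifest.  Output is byte-deterministic
    for fixed seeds.
    """
    labels = [label for label, _ in systems]
    if len(set(labels)) != len(labels):
        raise ParameterError(f"duplicate system labels: {labels}")
    if n_replicas < 1:
        raise ParameterError("need >= 1 replica")
    if geometry is None:
        geometry = make_toy_geometry()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    write_pdb(geometry.topology, out_dir / "topology.pdb")
    write_pdb(geometry.reference, out_dir / "reference.pdb")
    elements = geometry.topology.elements.tolist()

    manifest: dict = {
        "n_replicas": n_replicas,
        "topology": "topology.pdb",
        "reference": "reference.pdb",
        "ground_truth": "ground_truth.tsv",
        "systems": {},
    }
    gt_lines = ["system\treplica\tframe\tactive"]
    for label, base in systems:
        sys_dir = out_dir / label
        sys_dir.mkdir(exist_ok=True)
        files = []
        for r in range(1, n_replicas + 1):
            params = dataclasses.replace(
                base, seed=_replica_seed(base.seed, label, r)
            )
            states, traj = simulate_state_sequence(
                params, geometry, system_label=label, replica_index=r
            )
            rel = f"{label}/replica_{r:02d}.xyz"
            write_xyz_traj(traj.coords, elements, out_dir / rel,
                           comment=f"{label} replica {r}")
            files.append(rel)
            gt_lines.extend(
                f"{label}\t{r}\t{f}\t{int(s)}" for f, s in enumerate(states)
            )
        manifest["systems"][label] = {
            "params": dataclasses.asdict(base),
            "trajectories": files,
        }
    (out_dir / "ground_truth.tsv").write_text("\n".join(gt_lines) + "\n")
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    _write_config_stub(out_dir, labels, manifest)
    return manifest


def _write_config_stub(out_dir: Path, labels: Sequence[str],
                       manifest: dict) -> None:
    lines = [
        "reference_pdb: reference.pdb",
        "topology_pdb: topology.pdb",
        "frame_interval_ns: 1.0",
        "histogram_bin_width_A: 0.1",
        "output_dir: analysis",
        "criteria:",
        "  distance:",
        f"    res_a: {_ANCHOR_RES_A}",
        f"    res_b: {_ANCHOR_RES_B}",
        "    atom: CB",
        f"    cutoff_A: {_DISTANCE_CUTOFF_A}",
        "  rmsd:",
        f"    calc_residues: [{_HELIX_FIRST}, {_HELIX_LAST}]",
        f"    fit_residues: [{_CORE_FIRST}, 459]",
        "    atom: CA",
        f"    cutoff_A: {_RMSD_CUTOFF_A}",
        "systems:",
    ]
    for label in labels:
        lines.append(f"  - label: {label}")
        lines.append("    trajectories:")
        for rel in manifest["systems"][label]["trajectories"]:
            lines.append(f"      - {rel}")
    if len(labels) >= 2:
        lines.append("comparisons:")
        for a, b in zip(labels[::2], labels[1::2]):
            lines.append(f"  - [{a}, {b}]")
    (out_dir / "config.yaml").write_text("\n".join(lines) + "\n")
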