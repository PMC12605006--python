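"""Structure and trajectory I/O plus residue/atom selection.

Structures are held in :class:`StructureModel`, a thin array-backed record of
atoms with author residue numbering preserved exactly as read.  Trajectories
are ordered frame stacks congruent with a topology model.  Supported formats:
PDB (single- and multi-model), plain XYZ frame streams, and optionally DCD
when MDAnalysis is installed.  Coordinates are in Angstrom throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import (
    PDBParseError,
    SelectionError,
    TrajectoryFormatError,
)

__all__ = [
    "Atom",
    "StructureModel",
    "Trajectory",
    "SelectionSpec",
    "read_pdb",
    "write_pdb",
    "read_traj",
    "write_xyz_traj",
    "select_atoms",
    "fetch_pdb",
]


class Atom(NamedTuple):
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # (3,) Angstrom


@dataclass
class StructureModel:
    """A single structural model: per-atom identity plus Cartesian coordinates.

    Atom order is the file order and is preserved through round-trips.
    Residue numbers are author numbering; no renumbering is ever applied.
    """

    chain_ids: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise PDBParseError(
                f"coordinate array must be (n_atoms, 3), got {self.coords.shape}"
            )
        n = self.coords.shape[0]
        for name in ("chain_ids", "residue_numbers", "residue_names",
                     "atom_names", "elements"):
            arr = np.asarray(getattr(self, name))
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise PDBParseError(
                    f"annotation '{name}' has length {arr.shape}, expected ({n},)"
                )
        if not np.all(np.isfinite(self.coords)):
            raise PDBParseError("non-finite coordinates in structure model")
        keys = list(zip(self.chain_ids.tolist(),
                        self.residue_numbers.tolist(),
                        self.atom_names.tolist()))
        if len(set(keys)) != n:
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise PDBParseError(
                        f"duplicate atom key (chain, residue, atom) = {k}"
                    )
                seen.add(k)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def atoms(self) -> list[Atom]:
        return list(iter(self))

    def __iter__(self) -> Iterator[Atom]:
        for i in range(self.n_atoms):
            yield Atom(
                str(self.chain_ids[i]),
                int(self.residue_numbers[i]),
                str(self.residue_names[i]),
                str(self.atom_names[i]),
                str(self.elements[i]),
                self.coords[i],
            )

    def __len__(self) -> int:
        return self.n_atoms

    @classmethod
    def from_atoms(cls, atoms: Sequence[Atom]) -> "StructureModel":
        if not atoms:
            raise PDBParseError("cannot build a structure model from zero atoms")
        return cls(
            chain_ids=np.array([a.chain_id for a in atoms]),
            residue_numbers=np.array([a.residue_number for a in atoms], dtype=int),
            residue_names=np.array([a.residue_name for a in atoms]),
            atom_names=np.array([a.atom_name for a in atoms]),
            elements=np.array([a.element for a in atoms]),
            coords=np.array([a.position for a in atoms], dtype=float),
        )

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Copy of this model with replaced coordinates (identity unchanged)."""
        return StructureModel(
            chain_ids=self.chain_ids,
            residue_numbers=self.residue_numbers,
            residue_names=self.residue_names,
            atom_names=self.atom_names,
            elements=self.elements,
            coords=np.asarray(coords, dtype=float),
        )


@dataclass
class Trajectory:
    """Ordered coordinate frames for one replica of one system.

    ``coords`` has shape (n_frames, n_atoms, 3) and must be congruent with the
    topology used to read or generate it.  The frame interval is metadata
    supplied externally (XYZ streams carry no time axis).
    """

    coords: np.ndarray
    frame_interval_ns: float
    system_label: str = ""
    replica_index: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryFormatError(
                f"trajectory coords must be (n_frames, n_atoms, 3), "
                f"got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise TrajectoryFormatError("trajectory must contain >= 1 frame")
        if not self.frame_interval_ns > 0:
            raise TrajectoryFormatError(
                f"frame_interval_ns must be > 0, got {self.frame_interval_ns}"
            )
        if self.replica_index < 1:
            raise TrajectoryFormatError(
                f"replica_index must be >= 1, got {self.replica_index}"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def frames(self) -> np.ndarray:
        return self.coords

    @property
    def total_time_ns(self) -> float:
        return self.n_frames * self.frame_interval_ns


@dataclass(frozen=True)
class SelectionSpec:
    """Residue-range / atom-name selection in author numbering.

    ``residue_range`` is inclusive on both ends.  ``atom_names`` is a set of
    PDB atom names such as {"CA"} or {"CB"}.  ``chain_id`` of None matches any
    chain.
    """

    residue_range: tuple[int, int]
    atom_names: frozenset[str]
    chain_id: str | None = None

    def __post_init__(self) -> None:
        start, end = self.residue_range
        if start > end:
            raise SelectionError(
                f"selection residue range start {start} > end {end}"
            )
        object.__setattr__(self, "atom_names", frozenset(self.atom_names))
        if not self.atom_names:
            raise SelectionError("selection needs at least one atom name")

    @classmethod
    def single_atom(cls, residue: int, atom_name: str,
                    chain_id: str | None = None) -> "SelectionSpec":
        return cls((residue, residue), frozenset({atom_name}), chain_id)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _model_from_atom_array(arr: struc.AtomArray) -> StructureModel:
    return StructureModel(
        chain_ids=arr.chain_id.astype(str),
        residue_numbers=arr.res_id.astype(int),
        residue_names=arr.res_name.astype(str),
        atom_names=arr.atom_name.astype(str),
        elements=arr.element.astype(str),
        coords=np.asarray(arr.coord, dtype=float),
    )


def read_pdb(path: str | os.PathLike) -> StructureModel | list[StructureModel]:
    """Read a PDB file, preserving atom order and author residue numbering.

    Returns one :class:`StructureModel` for single-model files and a list
    (one per MODEL block, identical atom ordering) for multi-model files.
    """
    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"PDB file not found: {path}")
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except Exception as exc:  # biotite raises several error types here
        raise PDBParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if n_models == 0:
        raise PDBParseError(f"no ATOM/HETATM records in {path}")
    try:
        if n_models == 1:
            arr = pdb.get_structure(model=1, altloc="first")
            return _model_from_atom_array(arr)
        stack = pdb.get_structure(altloc="first")
    except Exception as exc:
        raise PDBParseError(f"malformed coordinates in {path}: {exc}") from exc
    template = _model_from_atom_array(stack[0])
    return [template.with_coords(stack.coord[i]) for i in range(n_models)]


def write_pdb(models: StructureModel | Sequence[StructureModel],
              path: str | os.PathLike) -> None:
    """Write one or more models (MODEL/ENDMDL for >1) to a PDB file."""
    if isinstance(models, StructureModel):
        models = [models]
    if not models:
        raise PDBParseError("no models to write")
    first = models[0]
    arr = struc.AtomArray(first.n_atoms)
    arr.chain_id = first.chain_ids.astype("U4")
    arr.res_id = first.residue_numbers
    arr.res_name = first.residue_names.astype("U5")
    arr.atom_name = first.atom_names.astype("U6")
    arr.element = first.elements.astype("U2")
    pdb = PDBFile()
    if len(models) == 1:
        arr.coord = np.asarray(first.coords, dtype=np.float32)
        pdb.set_structure(arr)
    else:
        stack = struc.stack([arr] * len(models))
        stack.coord = np.asarray(
            [m.coords for m in models], dtype=np.float32
        )
        pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# XYZ frame streams
# ---------------------------------------------------------------------------

def write_xyz_traj(traj_coords: np.ndarray, elements: Sequence[str],
                   path: str | os.PathLike,
                   comment: str = "") -> None:
    """Write an (n_frames, n_atoms, 3) coordinate stack as a plain XYZ stream.

    Coordinates are written with 3 decimals, which bounds round-trip error at
    5e-4 Angstrom.
    """
    coords = np.asarray(traj_coords, dtype=float)
    n_frames, n_atoms, _ = coords.shape
    if len(elements) != n_atoms:
        raise TrajectoryFormatError(
            f"{len(elements)} elements for {n_atoms} atoms"
        )
    with open(path, "w") as fh:
        for f in range(n_frames):
            fh.write(f"{n_atoms}\n")
            fh.write(f"{comment} frame {f}\n")
            for el, (x, y, z) in zip(elements, coords[f]):
                fh.write(f"{el} {x:.3f} {y:.3f} {z:.3f}\n")


def _read_xyz_frames(path: Path, n_atoms_expected: int) -> np.ndarray:
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame_idx = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        frame_idx += 1
        try:
            n_atoms = int(lines[i].split()[0])
        except (ValueError, IndexError) as exc:
            raise TrajectoryFormatError(
                f"{path}: bad atom-count line at line {i + 1}"
            ) from exc
        if n_atoms != n_atoms_expected:
            raise TrajectoryFormatError(
                f"{path}: frame {frame_idx} has {n_atoms} atoms, "
                f"topology has {n_atoms_expected}"
            )
        block = lines[i + 2:i + 2 + n_atoms]
        if len(block) < n_atoms:
            raise TrajectoryFormatError(
                f"{path}: frame {frame_idx} truncated "
                f"({len(block)} of {n_atoms} atom lines)"
            )
        try:
            frame = np.array(
                [ln.split()[1:4] for ln in block], dtype=float
            )
        except (ValueError, IndexError) as exc:
            raise TrajectoryFormatError(
                f"{path}: malformed atom line in frame {frame_idx}"
            ) from exc
        if frame.shape != (n_atoms, 3):
            raise TrajectoryFormatError(
                f"{path}: frame {frame_idx} has incomplete coordinates"
            )
        frames.append(frame)
        i += 2 + n_atoms
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames found")
    return np.array(frames)


def _read_dcd_frames(path: Path, n_atoms_expected: int) -> np.ndarray:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise TrajectoryFormatError(
            "DCD support requires MDAnalysis (install extra 'dcd')"
        ) from exc
    u = mda.Universe.empty(n_atoms_expected, trajectory=True)
    try:
        u.load_new(str(path))
    except Exception as exc:
        raise TrajectoryFormatError(
            f"{path}: cannot read DCD ({exc})"
        ) from exc
    frames = np.array([ts.positions.copy() for ts in u.trajectory],
                      dtype=float)
    if frames.shape[1] != n_atoms_expected:
        raise TrajectoryFormatError(
            f"{path}: DCD has {frames.shape[1]} atoms, "
            f"topology has {n_atoms_expected}"
        )
    return frames


def read_traj(path: str | os.PathLike, topology: StructureModel,
              frame_interval_ns: float, system_label: str = "",
              replica_index: int = 1) -> Trajectory:
    """Read a trajectory (XYZ, multi-model PDB, or DCD) against a topology.

    Every frame must carry exactly the topology's atom count, in topology
    order; a mismatch is reported with the offending frame index.
    """
    path = Path(path)
    if not path.exists():
        raise TrajectoryFormatError(f"trajectory file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        coords = _read_xyz_frames(path, topology.n_atoms)
    elif suffix in (".pdb", ".ent"):
        models = read_pdb(path)
        if isinstance(models, StructureModel):
            models = [models]
        for k, m in enumerate(models, start=1):
            if m.n_atoms != topology.n_atoms:
                raise TrajectoryFormatError(
                    f"{path}: frame {k} has {m.n_atoms} atoms, "
                    f"topology has {topology.n_atoms}"
                )
        coords = np.array([m.coords for m in models])
    elif suffix == ".dcd":
        coords = _read_dcd_frames(path, topology.n_atoms)
    else:
        raise TrajectoryFormatError(
            f"unsupported trajectory format '{suffix}' for {path}"
        )
    return Trajectory(coords, frame_interval_ns, system_label, replica_index)


def fetch_pdb(pdb_id: str, dest_dir: str | os.PathLike,
              timeout_s: float = 30.0) -> Path:
    """Download a PDB entry from RCSB into ``dest_dir``; returns the path.

    Cached: an existing ``<id>.pdb`` in ``dest_dir`` is reused without any
    network access.  Raises ``PDBParseError`` when the entry cannot be
    retrieved (e.g. offline).
    """
    import urllib.error
    import urllib.request

    pdb_id = pdb_id.lower()
    if not (len(pdb_id) == 4 and pdb_id.isalnum()):
        raise PDBParseError(f"not a valid PDB id: {pdb_id!r}")
    dest_dir = Path(dest_dir)
    dest_dir.mkdir(parents=True, exist_ok=True)
    dest = dest_dir / f"{pdb_id}.pdb"
    if dest.exists():
        return dest
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    try:
        with urllib.request.urlopen(url, timeout=timeout_s) as response:
            data = response.read()
    except (urllib.error.URLError, OSError) as exc:
        raise PDBParseError(
            f"could not fetch PDB entry {pdb_id} from {url}: {exc}"
        ) from exc
    dest.write_bytes(data)
    return dest


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_atoms(model: StructureModel, spec: SelectionSpec) -> np.ndarray:
    """Resolve a selection to an ordered array of atom indices.

    Indices are sorted by (chain, residue number, file order).  An empty
    result is an error, never an empty list: both state criteria depend on
    specific named atoms being present.
    """
    if model.n_atoms == 0:
        raise SelectionError("cannot select from an empty model")
    start, end = spec.residue_range
    mask = (
        (model.residue_numbers >= start)
        & (model.residue_numbers <= end)
        & np.isin(model.atom_names, sorted(spec.atom_names))
    )
    if spec.chain_id is not None:
        mask &= model.chain_ids == spec.chain_id
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise SelectionError(
            f"selection matched no atoms: residues {start}-{end}, "
            f"atoms {sorted(spec.atom_names)}, chain "
            f"{spec.chain_id or 'any'}"
        )
    order = np.lexsort((idx, model.residue_numbers[idx],
                        model.chain_ids[idx]))
    return idx[order]
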