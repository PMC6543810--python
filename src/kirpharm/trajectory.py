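"""Domain types and I/O for trajectory snapshots of the Kir6/ligand system.

Trajectories are stored as a fixed topology (ordered :class:`AtomRecord`
list) plus a dense (n_frames, n_atoms, 3) coordinate array in Angstrom and
a strictly increasing per-frame clock in nanoseconds. On disk the exchange
format is multi-model PDB (MODEL/ENDMDL) with a YAML selection config
declaring the ligand atoms, ligand fragments, PIP2 residues and the frame
spacing, which the coordinate format itself does not carry.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .geometry import interface_area as _interface_area
from .geometry import rmsd_series, vdw_radius

__all__ = [
    "AtomRecord",
    "Trajectory",
    "LigandFragmentMap",
    "SiteDefinition",
    "SelectionConfig",
    "TrajectoryParseError",
    "ConfigError",
    "load_trajectory",
    "write_trajectory",
    "decompose_ligand",
    "ligand_rmsd",
    "frame_interface_area",
    "CANONICAL_FRAGMENTS",
]

#: The five-part decomposition of a thiazolidinedione-like ligand: the
#: pyridine (RingA), benzene (RingB) and thiazolidinedione (RingC) rings
#: and the two connecting linkers.
CANONICAL_FRAGMENTS = ("RingA", "RingB", "RingC", "LinkerD", "LinkerE")


class TrajectoryParseError(ValueError):
    pass


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AtomRecord:
    """One topology atom; ``coordinates`` are its frame-0 position (A)."""

    atom_id: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    coordinates: tuple[float, float, float] = (0.0, 0.0, 0.0)
    is_ligand: bool = False
    is_pip2: bool = False

    def __post_init__(self) -> None:
        if self.atom_id < 1:
            raise ValueError("atom_id must be >= 1")
        if self.residue_number < 1:
            raise ValueError("residue_number must be >= 1")
        if not self.chain_id:
            raise ValueError("chain_id must be non-empty")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")


@dataclass
class Trajectory:
    atoms: list[AtomRecord]
    coords: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    times: np.ndarray  # ns, strictly increasing

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coords carry {self.coords.shape[1]} atoms but topology has "
                f"{len(self.atoms)}"
            )
        if self.times.shape != (self.coords.shape[0],):
            raise ValueError("times must have one entry per frame")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        self._id_to_index = {a.atom_id: i for i, a in enumerate(self.atoms)}
        if len(self._id_to_index) != len(self.atoms):
            raise ValueError("atom ids must be unique")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def indices_of(self, atom_ids: Iterable[int]) -> np.ndarray:
        try:
            return np.array([self._id_to_index[i] for i in atom_ids], dtype=int)
        except KeyError as exc:
            raise ConfigError(f"atom id {exc.args[0]} not in topology") from None

    @property
    def ligand_atom_ids(self) -> frozenset[int]:
        return frozenset(a.atom_id for a in self.atoms if a.is_ligand)

    def positions(self, frame: int, atom_ids: Iterable[int] | None = None) -> dict[int, np.ndarray]:
        """Mapping atom_id -> xyz for one frame (ligand atoms by default)."""
        ids = list(atom_ids) if atom_ids is not None else sorted(self.ligand_atom_ids)
        idx = self.indices_of(ids)
        return {i: self.coords[frame, j] for i, j in zip(ids, idx)}

    def radii(self) -> np.ndarray:
        return np.array([vdw_radius(a.element) for a in self.atoms])


@dataclass(frozen=True)
class LigandFragmentMap:
    """Named, pairwise-disjoint sets of ligand atom ids."""

    fragments: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("fragment map must be non-empty")
        seen: dict[int, str] = {}
        for name, ids in self.fragments.items():
            if not ids:
                raise ValueError(f"fragment {name!r} is empty")
            for i in ids:
                if i in seen:
                    raise ValueError(
                        f"fragments {seen[i]!r} and {name!r} share atom id {i}"
                    )
                seen[i] = name

    def fragment_of(self, atom_ids: Iterable[int]) -> str:
        """Fragment containing any of ``atom_ids``, else 'unassigned'."""
        for name, ids in self.fragments.items():
            if ids & set(atom_ids):
                return name
        return "unassigned"

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.fragments)


@dataclass(frozen=True)
class SiteDefinition:
    """A binding site as a residue selection plus a contact cutoff (A)."""

    chain_id: str
    residue_numbers: frozenset[int]
    cutoff: float = 4.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not self.residue_numbers:
            raise ValueError("residue set must be non-empty")


@dataclass
class SelectionConfig:
    """Ligand/PIP2/fragment declarations accompanying a multi-model PDB.

    ``dt`` is the frame spacing in ns; ``t0`` the clock of the first frame.
    ``chemistry`` holds the ligand atom-typing block consumed by the
    perception stage (bonds, aromatic atoms, donors/acceptors, ...).
    """

    ligand_atom_ids: frozenset[int]
    pip2_residues: frozenset[tuple[str, int]] = frozenset()  # (chain, resnum)
    fragments: dict[str, frozenset[int]] = field(default_factory=dict)
    dt: float = 1.0
    t0: float = 0.0
    chemistry: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SelectionConfig":
        text = Path(source).read_text() if isinstance(source, Path) else source
        if isinstance(source, str) and "\n" not in source and Path(source).exists():
            text = Path(source).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict) or "ligand_atom_ids" not in raw:
            raise ConfigError("selection config must declare ligand_atom_ids")
        pip2 = frozenset(
            (str(r["chain"]), int(r["residue"])) for r in raw.get("pip2_residues", [])
        )
        fragments = {
            str(k): frozenset(int(i) for i in v)
            for k, v in (raw.get("fragments") or {}).items()
        }
        return cls(
            ligand_atom_ids=frozenset(int(i) for i in raw["ligand_atom_ids"]),
            pip2_residues=pip2,
            fragments=fragments,
            dt=float(raw.get("dt", 1.0)),
            t0=float(raw.get("t0", 0.0)),
            chemistry=raw.get("chemistry") or {},
        )

    def to_yaml(self) -> str:
        doc = {
            "ligand_atom_ids": sorted(self.ligand_atom_ids),
            "pip2_residues": [
                {"chain": c, "residue": r} for c, r in sorted(self.pip2_residues)
            ],
            "fragments": {k: sorted(v) for k, v in self.fragments.items()},
            "dt": self.dt,
            "t0": self.t0,
            "chemistry": self.chemistry,
        }
        return yaml.safe_dump(doc, sort_keys=False)


def _validate_model_atom_counts(lines: Sequence[str]) -> None:
    # Cheap pre-scan so a malformed file fails with the model index named.
    counts: list[int] = []
    current: int | None = None
    saw_model = False
    for line in lines:
        rec = line[:6]
        if rec.startswith("MODEL"):
            saw_model = True
            current = 0
        elif rec in ("ATOM  ", "HETATM"):
            if current is None:
                current = 0
            current += 1
        elif rec.startswith("ENDMDL"):
            counts.append(current or 0)
            current = None
    if current is not None and (current > 0 or not saw_model):
        counts.append(current)
    if counts and any(c != counts[0] for c in counts):
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise TrajectoryParseError(
            f"model {bad + 1} has {counts[bad]} atoms but model 1 has {counts[0]}"
        )


def load_trajectory(source: str | Path, config: SelectionConfig) -> Trajectory:
    """Read a multi-model PDB plus selection config into a Trajectory.

    ``source`` may be a path or the raw PDB text. Ligand and PIP2 flags are
    set from the config; frame times are ``t0 + i*dt``.
    """
    from biotite.structure.io.pdb import PDBFile

    if isinstance(source, Path) or ("\n" not in str(source) and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    lines = text.splitlines()
    _validate_model_atom_counts(lines)
    pdb = PDBFile.read(io.StringIO(text))
    stack = pdb.get_structure(model=None, extra_fields=["atom_id"])
    n_atoms = stack.array_length()
    if n_atoms == 0:
        raise TrajectoryParseError("no atoms found")
    atom_ids = [int(i) for i in stack.atom_id]
    atoms = []
    for k in range(n_atoms):
        chain = str(stack.chain_id[k]) or "A"
        resnum = int(stack.res_id[k])
        aid = atom_ids[k]
        atoms.append(
            AtomRecord(
                atom_id=aid,
                name=str(stack.atom_name[k]),
                element=str(stack.element[k]) or "C",
                residue_name=str(stack.res_name[k]),
                residue_number=resnum,
                chain_id=chain,
                coordinates=tuple(np.asarray(stack.coord[0, k], dtype=float)),
                is_ligand=aid in config.ligand_atom_ids,
                is_pip2=(chain, resnum) in config.pip2_residues,
            )
        )
    present = {a.atom_id for a in atoms}
    missing = sorted(config.ligand_atom_ids - present)
    if missing:
        raise ConfigError(f"configured ligand atom ids missing from structure: {missing}")
    for frag, ids in config.fragments.items():
        gone = sorted(set(ids) - present)
        if gone:
            raise ConfigError(f"fragment {frag!r} references missing atom ids: {gone}")
    n_frames = stack.stack_depth()
    times = config.t0 + config.dt * np.arange(n_frames)
    return Trajectory(atoms=atoms, coords=np.asarray(stack.coord, dtype=float), times=times)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as multi-model PDB (coordinates to 1e-3 A)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    stack = struc.AtomArrayStack(traj.n_frames, traj.n_atoms)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    stack.set_annotation("chain_id", np.array([a.chain_id for a in traj.atoms], dtype="U4"))
    stack.set_annotation("res_id", np.array([a.residue_number for a in traj.atoms]))
    stack.set_annotation("res_name", np.array([a.residue_name for a in traj.atoms], dtype="U5"))
    stack.set_annotation("atom_name", np.array([a.name for a in traj.atoms], dtype="U6"))
    stack.set_annotation("element", np.array([a.element.upper() for a in traj.atoms], dtype="U2"))
    stack.set_annotation(
        "hetero", np.array([a.is_ligand or a.is_pip2 for a in traj.atoms], dtype=bool)
    )
    stack.set_annotation("atom_id", np.array([a.atom_id for a in traj.atoms]))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def decompose_ligand(
    traj: Trajectory, fragment_config: Mapping[str, Iterable[int]]
) -> LigandFragmentMap:
    """Validate and freeze a named fragment decomposition of the ligand."""
    ligand = traj.ligand_atom_ids
    frozen: dict[str, frozenset[int]] = {}
    for name, ids in fragment_config.items():
        ids = frozenset(int(i) for i in ids)
        stray = sorted(ids - ligand)
        if stray:
            raise ConfigError(
                f"fragment {name!r} contains non-ligand or unknown atom ids: {stray}"
            )
        frozen[str(name)] = ids
    return LigandFragmentMap(fragments=frozen)


def ligand_rmsd(
    traj: Trajectory,
    analyze_atom_ids: Iterable[int],
    fit_atom_ids: Iterable[int],
    reference: int = 0,
) -> np.ndarray:
    """Per-frame RMSD (A) of one selection after rigid fit on another."""
    return rmsd_series(
        traj.coords,
        traj.indices_of(analyze_atom_ids),
        traj.indices_of(fit_atom_ids),
        reference=reference,
    )


def frame_interface_area(
    traj: Trajectory,
    frame: int,
    ligand_atom_ids: Iterable[int],
    receptor_atom_ids: Iterable[int],
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """Buried ligand-receptor interface area (nm^2) in one frame."""
    return _interface_area(
        traj.coords[frame],
        traj.radii(),
        traj.indices_of(ligand_atom_ids),
        traj.indices_of(receptor_atom_ids),
        probe_radius=probe_radius,
        n_points=n_points,
    )
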