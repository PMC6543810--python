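"""Per-frame pharmacophore feature perception and interaction detection.

Features live on the ligand: hydrophobic (H) centroids of apolar-carbon
clusters, aromatic (AR) ring centroids with normals, hydrogen-bond donors
(HBD) and acceptors (HBA) on heavy atoms, and positive-ionizable (PI)
points on protonatable nitrogens. Atom typing (bonds, aromaticity,
donors/acceptors, charges) is declared in the ligand chemistry config
rather than inferred, so perception is deterministic and testable.

Interactions are scored against the receptor scope the caller provides —
by convention protein plus PIP2, with bulk lipid (POPC) and water excluded.
The geometric cutoffs are conventional defaults, configurable per rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .trajectory import LigandFragmentMap, Trajectory

__all__ = [
    "FEATURE_KINDS",
    "FeaturePoint",
    "InteractionRecord",
    "PerceptionRules",
    "LigandChemistry",
    "ReceptorView",
    "receptor_view",
    "perceive_features",
    "detect_interactions",
]

FEATURE_KINDS = ("H", "AR", "HBD", "HBA", "PI")
INTERACTION_KINDS = ("H", "AR", "HB_donor", "HB_acceptor", "PI")

#: record kind -> the ligand feature kind it involves
_RECORD_TO_FEATURE = {
    "H": "H",
    "AR": "AR",
    "HB_donor": "HBD",
    "HB_acceptor": "HBA",
    "PI": "PI",
}


@dataclass(frozen=True)
class FeaturePoint:
    kind: str
    center: tuple[float, float, float]
    ligand_atom_ids: frozenset[int]
    direction: tuple[float, float, float] | None = None
    r_tol: float = 1.5

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.r_tol <= 0:
            raise ValueError("r_tol must be positive")
        if self.direction is not None:
            n = float(np.linalg.norm(self.direction))
            if abs(n - 1.0) > 1e-6:
                raise ValueError("direction must be unit-normalised")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    def moved(self, center: np.ndarray, direction: np.ndarray | None = None) -> "FeaturePoint":
        return FeaturePoint(
            kind=self.kind,
            center=tuple(float(x) for x in center),
            ligand_atom_ids=self.ligand_atom_ids,
            direction=None if direction is None else tuple(float(x) for x in direction),
            r_tol=self.r_tol,
        )


@dataclass(frozen=True)
class InteractionRecord:
    frame_index: int
    kind: str  # H, AR, HB_donor, HB_acceptor, PI
    ligand_atom_ids: frozenset[int]
    fragment_name: str
    partner: tuple[str, int, str]  # residue_name ("PIP2" for lipid), number, chain
    distance: float
    angle: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in INTERACTION_KINDS:
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if self.distance <= 0:
            raise ValueError("distance must be positive")

    @property
    def feature_kind(self) -> str:
        return _RECORD_TO_FEATURE[self.kind]


@dataclass(frozen=True)
class PerceptionRules:
    """Geometric cutoffs for perception and interaction detection.

    Defaults are reimplementation conventions (A / degrees): apolar C-C
    4.5; AR centroid 5.0 with <=30 deg normal tilt; H-bond heavy-atom 3.5
    with D-H...A >= 130 deg (angle test skipped when no H direction is
    known); charged N to anionic O 5.6. ``r_tol`` is the screening
    tolerance radius stamped on every perceived feature.
    """

    h_cutoff: float = 4.5
    ar_distance: float = 5.0
    ar_angle: float = 30.0
    hb_distance: float = 3.5
    hb_angle: float = 130.0
    pi_cutoff: float = 5.6
    r_tol: float = 1.5
    r_tol_by_kind: dict = field(default_factory=dict)

    def tol(self, kind: str) -> float:
        return float(self.r_tol_by_kind.get(kind, self.r_tol))


@dataclass
class LigandChemistry:
    """Declared ligand atom typing (no on-the-fly protonation prediction)."""

    bonds: tuple[tuple[int, int], ...] = ()
    aromatic_atoms: frozenset[int] = frozenset()
    aromatic_rings: tuple[frozenset[int], ...] = ()  # explicit override
    hydrophobic_groups: tuple[frozenset[int], ...] = ()  # explicit override
    apolar_carbons: frozenset[int] = frozenset()  # explicit override
    donors: frozenset[int] = frozenset()
    acceptors: frozenset[int] = frozenset()
    pi_nitrogens: frozenset[int] = frozenset()
    donor_hydrogens: dict[int, int] = field(default_factory=dict)

    @classmethod
    def from_config(cls, raw: Mapping) -> "LigandChemistry":
        def fs(key):
            return frozenset(int(i) for i in raw.get(key, []))

        return cls(
            bonds=tuple((int(a), int(b)) for a, b in raw.get("bonds", [])),
            aromatic_atoms=fs("aromatic_atoms"),
            aromatic_rings=tuple(
                frozenset(int(i) for i in ring) for ring in raw.get("aromatic_rings", [])
            ),
            hydrophobic_groups=tuple(
                frozenset(int(i) for i in grp) for grp in raw.get("hydrophobic_groups", [])
            ),
            apolar_carbons=fs("apolar_carbons"),
            donors=fs("donors"),
            acceptors=fs("acceptors"),
            pi_nitrogens=fs("pi_nitrogens"),
            donor_hydrogens={int(k): int(v) for k, v in (raw.get("donor_hydrogens") or {}).items()},
        )


def _plane_normal(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    n = vt[-1]
    return n / np.linalg.norm(n)


def _bond_graph(chem: LigandChemistry, nodes: Iterable[int]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((a, b) for a, b in chem.bonds if a in g and b in g)
    return g


def perceive_features(
    positions: Mapping[int, np.ndarray],
    elements: Mapping[int, str],
    chem: LigandChemistry,
    rules: PerceptionRules | None = None,
) -> list[FeaturePoint]:
    """Perceive ligand pharmacophore features for one frame.

    ``positions`` maps ligand atom id -> xyz (A); ``elements`` maps atom id
    -> element symbol. Output order is deterministic: AR rings, H clusters,
    HBD, HBA, PI, each sorted by member atom ids.
    """
    rules = rules or PerceptionRules()
    feats: list[FeaturePoint] = []

    # aromatic rings
    rings: list[frozenset[int]] = list(chem.aromatic_rings)
    if not rings and chem.aromatic_atoms:
        if not chem.bonds:
            raise ValueError("ring perception requires a bond list")
        sub = _bond_graph(chem, chem.aromatic_atoms & positions.keys())
        rings = [frozenset(c) for c in nx.cycle_basis(sub) if len(c) >= 3]
    for ring in sorted(rings, key=lambda r: sorted(r)):
        pts = np.array([positions[i] for i in sorted(ring)])
        feats.append(
            FeaturePoint(
                kind="AR",
                center=tuple(pts.mean(axis=0)),
                ligand_atom_ids=ring,
                direction=tuple(_plane_normal(pts)),
                r_tol=rules.tol("AR"),
            )
        )

    # hydrophobic clusters
    groups: list[frozenset[int]] = list(chem.hydrophobic_groups)
    if not groups:
        apolar = set(chem.apolar_carbons)
        if not apolar:
            neigh: dict[int, set[int]] = {}
            for a, b in chem.bonds:
                neigh.setdefault(a, set()).add(b)
                neigh.setdefault(b, set()).add(a)
            for i in positions:
                if elements.get(i, "C").upper() != "C":
                    continue
                partners = neigh.get(i, set())
                if any(elements.get(j, "").upper() in ("N", "O") for j in partners):
                    continue
                apolar.add(i)
        sub = _bond_graph(chem, apolar & positions.keys())
        groups = [frozenset(c) for c in nx.connected_components(sub)]
    for grp in sorted(groups, key=lambda g: sorted(g)):
        pts = np.array([positions[i] for i in sorted(grp)])
        feats.append(
            FeaturePoint(
                kind="H",
                center=tuple(pts.mean(axis=0)),
                ligand_atom_ids=grp,
                r_tol=rules.tol("H"),
            )
        )

    for kind, ids in (("HBD", chem.donors), ("HBA", chem.acceptors), ("PI", chem.pi_nitrogens)):
        for i in sorted(ids):
            if i not in positions:
                continue
            direction = None
            if kind == "HBD":
                h = chem.donor_hydrogens.get(i)
                if h is not None and h in positions:
                    v = np.asarray(positions[h]) - np.asarray(positions[i])
                    n = np.linalg.norm(v)
                    if n > 0:
                        direction = tuple(v / n)
            feats.append(
                FeaturePoint(
                    kind=kind,
                    center=tuple(np.asarray(positions[i], dtype=float)),
                    ligand_atom_ids=frozenset([i]),
                    direction=direction,
                    r_tol=rules.tol(kind),
                )
            )
    return feats


# ---------------------------------------------------------------------------
# receptor typing
# ---------------------------------------------------------------------------

_HYDROPHOBIC_SIDECHAIN = {
    "ALA": {"CB"},
    "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1", "CD"},
    "MET": {"CB", "CG", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "PRO": {"CB", "CG", "CD"},
    "LYS": {"CB", "CG", "CD"},
    "ARG": {"CB", "CG"},
    "THR": {"CG2"},
    "GLU": {"CB", "CG"},
    "GLN": {"CB", "CG"},
}

_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1"},
}

_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "TRP": {"NE1"},
    "HIS": {"NE2"},
}

_ANIONIC = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}

_AROMATIC_RING_ATOMS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [("CG", "CD1", "CD2", "NE1", "CE2"), ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")],
}

_STANDARD_AA = set(_HYDROPHOBIC_SIDECHAIN) | set(_SIDECHAIN_ACCEPTORS) | set(
    _SIDECHAIN_DONORS
) | {"GLY", "CYS", "ASP", "HIS", "SER", "ASN"}

_EXCLUDED_RESNAMES = {"POPC", "POPE", "HOH", "SOL", "WAT", "TIP3", "K", "CL", "NA"}


@dataclass
class ReceptorView:
    """Typed receptor atoms of one frame (protein + PIP2 scope by default)."""

    positions: np.ndarray  # (m, 3)
    partners: list[tuple[str, int, str]]  # per atom: (resname, resnum, chain)
    apolar: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    anionic: np.ndarray
    rings: list[tuple[tuple[str, int, str], np.ndarray, np.ndarray]]  # partner, centroid, normal


def receptor_view(
    traj: Trajectory,
    frame: int,
    include_pip2: bool = True,
    include_resnames: Iterable[str] = (),
) -> ReceptorView:
    """Build the typed receptor scope for one frame.

    Only protein residues and (optionally) PIP2 are included; bulk lipid
    and water residues are dropped so they can never appear as interaction
    partners. ``include_resnames`` whitelists additional residue names.
    """
    include_extra = {r.upper() for r in include_resnames}
    sel: list[int] = []
    for k, a in enumerate(traj.atoms):
        if a.is_ligand:
            continue
        rn = a.residue_name.upper()
        if a.is_pip2:
            if include_pip2:
                sel.append(k)
        elif rn in _STANDARD_AA or rn in include_extra:
            sel.append(k)
    positions = traj.coords[frame, sel]
    partners: list[tuple[str, int, str]] = []
    apolar = np.zeros(len(sel), dtype=bool)
    donor = np.zeros(len(sel), dtype=bool)
    acceptor = np.zeros(len(sel), dtype=bool)
    anionic = np.zeros(len(sel), dtype=bool)
    by_residue: dict[tuple[str, int, str], dict[str, int]] = {}
    for m, k in enumerate(sel):
        a = traj.atoms[k]
        rn = "PIP2" if a.is_pip2 else a.residue_name.upper()
        partner = (rn, a.residue_number, a.chain_id)
        partners.append(partner)
        by_residue.setdefault(partner, {})[a.name.upper()] = m
        name = a.name.upper()
        el = a.element.upper()
        if a.is_pip2:
            # PIP2: hydrocarbon tail/ring carbons apolar; oxygens are
            # acceptors, phosphate oxygens anionic.
            apolar[m] = el == "C"
            acceptor[m] = el == "O"
            anionic[m] = el == "O" and ("P" in name or name.startswith("OP"))
        else:
            apolar[m] = name in _HYDROPHOBIC_SIDECHAIN.get(rn, set())
            acceptor[m] = name in ({"O", "OXT"} | _SIDECHAIN_ACCEPTORS.get(rn, set()))
            donor[m] = (name == "N" and rn != "PRO") or name in _SIDECHAIN_DONORS.get(rn, set())
            anionic[m] = name in _ANIONIC.get(rn, set()) or name == "OXT"
    rings = []
    for partner, atom_map in by_residue.items():
        for ring_names in _AROMATIC_RING_ATOMS.get(partner[0], []):
            idx = [atom_map[n] for n in ring_names if n in atom_map]
            if len(idx) >= 3:
                pts = positions[idx]
                rings.append((partner, pts.mean(axis=0), _plane_normal(pts)))
    return ReceptorView(
        positions=positions,
        partners=partners,
        apolar=apolar,
        donor=donor,
        acceptor=acceptor,
        anionic=anionic,
        rings=rings,
    )


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def detect_interactions(
    positions: Mapping[int, np.ndarray],
    features: Sequence[FeaturePoint],
    receptor: ReceptorView,
    rules: PerceptionRules | None = None,
    fragments: LigandFragmentMap | None = None,
    frame_index: int = 0,
) -> list[InteractionRecord]:
    """Geometric ligand-receptor interaction records for one frame.

    One record per (feature, partner residue) pair satisfying the rule for
    the feature's kind; the minimum qualifying distance is recorded.
    """
    rules = rules or PerceptionRules()
    records: list[InteractionRecord] = []

    def frag(ids: frozenset[int]) -> str:
        return fragments.fragment_of(ids) if fragments is not None else "unassigned"

    def emit(kind: str, feat: FeaturePoint, hits: dict, angles: dict | None = None) -> None:
        for partner in sorted(hits, key=lambda p: (p[2], p[1], p[0])):
            records.append(
                InteractionRecord(
                    frame_index=frame_index,
                    kind=kind,
                    ligand_atom_ids=feat.ligand_atom_ids,
                    fragment_name=frag(feat.ligand_atom_ids),
                    partner=partner,
                    distance=float(hits[partner]),
                    angle=None if angles is None else angles.get(partner),
                )
            )

    for feat in features:
        if feat.kind == "H":
            member_pts = np.array([positions[i] for i in sorted(feat.ligand_atom_ids)])
            mask = receptor.apolar
            if mask.any():
                rec_pts = receptor.positions[mask]
                d = np.linalg.norm(member_pts[:, None, :] - rec_pts[None, :, :], axis=2)
                best = d.min(axis=0)
                hits: dict = {}
                for m, within in enumerate(best <= rules.h_cutoff):
                    if within:
                        partner = [p for p, f in zip(receptor.partners, mask) if f][m]
                        if partner not in hits or best[m] < hits[partner]:
                            hits[partner] = best[m]
                emit("H", feat, hits)
        elif feat.kind == "AR":
            hits, angles = {}, {}
            for partner, centroid, normal in receptor.rings:
                d = float(np.linalg.norm(feat.xyz - centroid))
                if d > rules.ar_distance:
                    continue
                tilt = _angle_deg(np.asarray(feat.direction), normal)
                tilt = min(tilt, 180.0 - tilt)
                if tilt <= rules.ar_angle and (partner not in hits or d < hits[partner]):
                    hits[partner] = d
                    angles[partner] = tilt
            emit("AR", feat, hits, angles)
        elif feat.kind in ("HBD", "HBA"):
            mask = receptor.acceptor if feat.kind == "HBD" else receptor.donor
            if not mask.any():
                continue
            rec_pts = receptor.positions[mask]
            rec_partners = [p for p, f in zip(receptor.partners, mask) if f]
            d = np.linalg.norm(rec_pts - feat.xyz, axis=1)
            hits, angles = {}, {}
            for m in np.nonzero(d <= rules.hb_distance)[0]:
                ang = None
                if feat.kind == "HBD" and feat.direction is not None:
                    h_pos = feat.xyz + np.asarray(feat.direction)  # 1 A along D-H
                    ang = _angle_deg(feat.xyz - h_pos, rec_pts[m] - h_pos)
                    if ang < rules.hb_angle:
                        continue
                partner = rec_partners[m]
                if partner not in hits or d[m] < hits[partner]:
                    hits[partner] = d[m]
                    angles[partner] = ang
            emit("HB_donor" if feat.kind == "HBD" else "HB_acceptor", feat, hits, angles)
        elif feat.kind == "PI":
            mask = receptor.anionic
            if not mask.any():
                continue
            rec_pts = receptor.positions[mask]
            rec_partners = [p for p, f in zip(receptor.partners, mask) if f]
            d = np.linalg.norm(rec_pts - feat.xyz, axis=1)
            hits = {}
            for m in np.nonzero(d <= rules.pi_cutoff)[0]:
                partner = rec_partners[m]
                if partner not in hits or d[m] < hits[partner]:
                    hits[partner] = d[m]
            emit("PI", feat, hits)
    return records
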