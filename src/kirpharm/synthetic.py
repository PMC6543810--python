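"""Seeded generators for every input the analysis stages consume.

These generators emulate the *statistical structure* of the study inputs
— not their physics. The feature-trajectory generator draws per-frame
pharmacophore regimes from a categorical distribution whose default
probabilities (0.9552, 0.0120, 0.0120, 0.0120, 0.0088) put the expected
dominant-model count over 5,000 frames at 4,776, mirroring the published
ensemble structure for a thiazolidinedione ligand at the Kir6.1 PIP2-side
site. Umbrella windows are exact Boltzmann samples of stated analytic
potentials under the harmonic bias; dose-response tables are Hill curves
plus Gaussian noise; screening libraries plant actives around
representative models and geometry-scrambled decoys.

All generators are bit-reproducible under (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dose_response import DoseResponseTable, hill
from .perception import FeaturePoint, InteractionRecord
from .pharmacophore import (
    Molecule,
    PharmacophoreModel,
    RepresentativeModel,
    build_frame_model,
)
from .pmf import KB, UmbrellaWindow
from .trajectory import AtomRecord, LigandFragmentMap, Trajectory

__all__ = [
    "RegimeSpec",
    "EnsembleSpec",
    "SyntheticEnsemble",
    "PotentialSpec",
    "ScreenLibrary",
    "default_ensemble_spec",
    "gen_feature_trajectory",
    "gen_us_windows",
    "gen_dose_response",
    "gen_screen_library",
]

_FEATURE_TO_RECORD = {"H": "H", "AR": "AR", "HBD": "HB_donor", "HBA": "HB_acceptor", "PI": "PI"}
_NOMINAL_DISTANCE = {"H": 4.0, "AR": 4.5, "HB_donor": 3.0, "HB_acceptor": 3.0, "PI": 5.0}


@dataclass(frozen=True)
class RegimeSpec:
    """One per-frame model regime: which features appear, with whom they
    interact, and how often the regime occurs."""

    name: str
    feature_indices: tuple[int, ...]
    partners: Mapping[int, tuple[tuple[str, int, str], ...]]
    probability: float


@dataclass
class EnsembleSpec:
    feature_templates: tuple[FeaturePoint, ...]
    regimes: tuple[RegimeSpec, ...]
    jitter_sigma: float = 0.3  # Angstrom
    n_frames: int = 5000

    def __post_init__(self) -> None:
        probs = np.array([r.probability for r in self.regimes])
        if np.any(probs <= 0):
            raise ValueError("regime probabilities must be positive")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"regime probabilities sum to {probs.sum()!r}, not 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter sigma must be >= 0")

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([r.probability for r in self.regimes])


@dataclass
class SyntheticEnsemble:
    """Generated trajectory with its per-frame features and interactions."""

    trajectory: Trajectory
    fragments: LigandFragmentMap
    frame_features: list[list[FeaturePoint]]
    frame_records: list[list[InteractionRecord]]
    regime_labels: np.ndarray
    spec: EnsembleSpec

    def frame_models(self) -> list[PharmacophoreModel]:
        return [
            build_frame_model(recs, feats)
            for recs, feats in zip(self.frame_records, self.frame_features)
        ]


def _hexagon(center, radius=1.39, z=0.0):
    ang = np.linspace(0, 2 * np.pi, 7)[:-1]
    return np.column_stack(
        (center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang), np.full(6, z))
    )


def _default_ligand():
    """RSG-like synthetic ligand: two aromatic rings, an ether linker, a
    methylene bridge and a thiazolidinedione head with an N-H donor and two
    carbonyl acceptors. Heavy atoms only; ids 1-22."""
    coords: dict[int, np.ndarray] = {}
    elements: dict[int, str] = {}
    # Ring A (pyridine): N1, C2-C6
    ring_a = _hexagon((0.0, 0.0))
    for i, p in enumerate(ring_a, start=1):
        coords[i] = p
        elements[i] = "N" if i == 1 else "C"
    # Linker D: C7 (N-methyl carbon stand-in), O8 (ether)
    coords[7] = np.array([2.6, 0.8, 0.3])
    elements[7] = "C"
    coords[8] = np.array([3.9, 0.1, 0.2])
    elements[8] = "O"
    # Ring B (benzene): C9-C14
    ring_b = _hexagon((6.2, 0.0))
    for i, p in enumerate(ring_b, start=9):
        coords[i] = p
        elements[i] = "C"
    # Linker E: C15 methylene bridge
    coords[15] = np.array([8.6, 0.6, 0.4])
    elements[15] = "C"
    # Ring C (thiazolidinedione): S16, C17, N18, C19, C20 + O21, O22
    base = np.array([10.6, 0.0, 0.0])
    ring_c = {
        16: base + [0.0, 1.2, 0.0],
        17: base + [1.1, 0.4, 0.2],
        18: base + [1.0, -1.0, 0.1],
        19: base + [-0.3, -1.2, -0.1],
        20: base + [-0.9, 0.0, -0.2],
    }
    coords.update(ring_c)
    elements.update({16: "S", 17: "C", 18: "N", 19: "C", 20: "C"})
    coords[21] = base + [2.2, 0.9, 0.4]  # carbonyl O on C17
    coords[22] = base + [-0.8, -2.3, -0.2]  # carbonyl O on C19
    elements[21] = elements[22] = "O"
    fragments = {
        "RingA": frozenset(range(1, 7)),
        "LinkerD": frozenset({7, 8}),
        "RingB": frozenset(range(9, 15)),
        "LinkerE": frozenset({15}),
        "RingC": frozenset(range(16, 23)),
    }
    chemistry = {
        "bonds": [[1, 2], [2, 3], [3, 4], [4, 5], [5, 6], [6, 1],
                  [2, 7], [7, 8], [8, 9],
                  [9, 10], [10, 11], [11, 12], [12, 13], [13, 14], [14, 9],
                  [12, 15], [15, 17],
                  [16, 17], [17, 18], [18, 19], [19, 20], [20, 16],
                  [17, 21], [19, 22]],
        "aromatic_rings": [list(range(1, 7)), list(range(9, 15))],
        "hydrophobic_groups": [[2, 3, 4, 5, 6], list(range(9, 15)), [15]],
        "donors": [18],
        "acceptors": [21, 22],
        "pi_nitrogens": [],
    }
    return coords, elements, fragments, chemistry


def _stub_receptor():
    """A minimal binding-site shell: the hydrophobic contacts of the slide
    helix / TM2 pocket, a backbone acceptor, a serine donor, one PIP2 head
    group and one bulk POPC lipid (the latter present only to exercise the
    receptor-scope exclusion)."""
    spec = [
        # (atom_id, name, element, resname, resnum, chain, xyz, is_pip2)
        (101, "O", "O", "LEU", 57, "A", (14.3, -2.2, 0.3), False),
        (102, "CB", "C", "LEU", 57, "A", (15.5, -3.2, 0.7), False),
        (103, "CD1", "C", "TRP", 69, "A", (8.9, 4.3, 0.8), False),
        (104, "CB", "C", "TRP", 69, "A", (9.8, 5.2, 0.4), False),
        (105, "CG", "C", "PHE", 76, "A", (0.0, 4.3, 1.2), False),
        (106, "CZ", "C", "PHE", 76, "A", (0.8, 5.6, 1.9), False),
        (107, "OG", "O", "SER", 79, "A", (9.9, -5.2, -0.3), False),
        (108, "CG", "C", "PHE", 80, "A", (6.4, 4.2, -0.6), False),
        (109, "CG1", "C", "VAL", 172, "A", (-3.6, -3.2, 0.8), False),
        (110, "CB", "C", "VAL", 172, "A", (-4.8, -4.0, 1.2), False),
        (111, "CE", "C", "MET", 173, "A", (-4.2, 1.9, -0.6), False),
        (112, "P1", "P", "PIP", 2001, "A", (14.6, 3.0, 0.6), True),
        (113, "O1P", "O", "PIP", 2001, "A", (15.3, 2.3, 1.1), True),
        (114, "O2P", "O", "PIP", 2001, "A", (15.8, 3.8, 1.4), True),
        (115, "C1", "C", "POP", 3001, "A", (5.0, -8.0, 4.0), False),
        (116, "C2", "C", "POP", 3001, "A", (6.2, -8.8, 4.4), False),
    ]
    atoms = [
        AtomRecord(
            atom_id=i, name=n, element=e, residue_name=rn, residue_number=num,
            chain_id=ch, coordinates=xyz, is_ligand=False, is_pip2=pip,
        )
        for i, n, e, rn, num, ch, xyz, pip in spec
    ]
    return atoms


def default_ensemble_spec(n_frames: int = 5000, jitter_sigma: float = 0.3) -> EnsembleSpec:
    """The default five-regime ensemble.

    All regimes share the two hydrophobic features on the pyridine and the
    benzene rings. The dominant regime adds the thiazolidinedione N-H
    donor; the minority regimes drop it, add one of the carbonyl
    acceptors, or both — a family of five distinct identity keys whose
    expected dominant share over 5,000 frames is 95.52%.
    """
    coords, _elements, fragments, _chem = _default_ligand()

    def centroid(ids):
        return tuple(np.mean([coords[i] for i in ids], axis=0))

    templates = (
        FeaturePoint(kind="H", center=centroid([2, 3, 4, 5, 6]), ligand_atom_ids=frozenset({2, 3, 4, 5, 6})),
        FeaturePoint(kind="H", center=centroid(range(9, 15)), ligand_atom_ids=frozenset(range(9, 15))),
        FeaturePoint(kind="HBD", center=tuple(coords[18]), ligand_atom_ids=frozenset({18})),
        FeaturePoint(kind="HBA", center=tuple(coords[21]), ligand_atom_ids=frozenset({21})),
        FeaturePoint(kind="HBA", center=tuple(coords[22]), ligand_atom_ids=frozenset({22})),
    )
    ring_a_partners = (("PHE", 76, "A"), ("VAL", 172, "A"), ("MET", 173, "A"))
    ring_b_partners = (("PHE", 80, "A"),)
    nh_partner = (("LEU", 57, "A"),)
    o21_partner = (("PIP2", 2001, "A"),)
    o22_partner = (("SER", 79, "A"),)
    base = {0: ring_a_partners, 1: ring_b_partners}
    regimes = (
        RegimeSpec("M1", (0, 1, 2), {**base, 2: nh_partner}, 0.9552),
        RegimeSpec("M2", (0, 1), base, 0.0120),
        RegimeSpec("M3", (0, 1, 2, 3), {**base, 2: nh_partner, 3: o21_partner}, 0.0120),
        RegimeSpec("M4", (0, 1, 2, 4), {**base, 2: nh_partner, 4: o22_partner}, 0.0120),
        RegimeSpec("M5", (0, 1, 3), {**base, 3: o21_partner}, 0.0088),
    )
    return EnsembleSpec(
        feature_templates=templates,
        regimes=regimes,
        jitter_sigma=jitter_sigma,
        n_frames=n_frames,
    )


def gen_feature_trajectory(spec: EnsembleSpec, seed: int) -> SyntheticEnsemble:
    """Draw a per-frame regime sequence and emit features plus records.

    Per frame the regime is drawn from the categorical distribution; its
    template features are jittered with isotropic Gaussian noise on the
    centers and paired with interaction records against the stub receptor.
    The returned trajectory carries jittered ligand coordinates over a
    100 ns clock (dt = 100 ns / n_frames), so the coordinate-level
    operations (RMSD, occupancy, PDB round trips) work on the same object.
    """
    rng = np.random.default_rng(seed)
    coords, elements, fragments, chemistry = _default_ligand()
    frag_map = LigandFragmentMap(
        fragments={k: frozenset(v) for k, v in fragments.items()}
    )
    n = spec.n_frames
    regime_idx = rng.choice(len(spec.regimes), size=n, p=spec.probabilities)

    lig_ids = sorted(coords)
    base_xyz = np.array([coords[i] for i in lig_ids])
    lig_noise = rng.normal(0.0, spec.jitter_sigma, size=(n, len(lig_ids), 3))
    receptor_atoms = _stub_receptor()
    rec_xyz = np.array([a.coordinates for a in receptor_atoms])

    frame_features: list[list[FeaturePoint]] = []
    frame_records: list[list[InteractionRecord]] = []
    for f in range(n):
        regime = spec.regimes[regime_idx[f]]
        feats: list[FeaturePoint] = []
        recs: list[InteractionRecord] = []
        for t_idx in regime.feature_indices:
            template = spec.feature_templates[t_idx]
            offset = rng.normal(0.0, spec.jitter_sigma, size=3)
            feat = template.moved(template.xyz + offset)
            feats.append(feat)
            kind = _FEATURE_TO_RECORD[feat.kind]
            for partner in regime.partners.get(t_idx, ()):
                recs.append(
                    InteractionRecord(
                        frame_index=f,
                        kind=kind,
                        ligand_atom_ids=feat.ligand_atom_ids,
                        fragment_name=frag_map.fragment_of(feat.ligand_atom_ids),
                        partner=partner,
                        distance=_NOMINAL_DISTANCE[kind],
                    )
                )
        frame_features.append(feats)
        frame_records.append(recs)

    lig_atoms = [
        AtomRecord(
            atom_id=i,
            name=f"{elements[i]}{i}",
            element=elements[i],
            residue_name="RSG",
            residue_number=1,
            chain_id="L",
            coordinates=tuple(coords[i]),
            is_ligand=True,
        )
        for i in lig_ids
    ]
    all_atoms = lig_atoms + receptor_atoms
    traj_coords = np.empty((n, len(all_atoms), 3))
    traj_coords[:, : len(lig_ids)] = base_xyz[None, :, :] + lig_noise
    traj_coords[:, len(lig_ids):] = rec_xyz[None, :, :]
    dt = 100.0 / n
    trajectory = Trajectory(atoms=all_atoms, coords=traj_coords, times=dt * np.arange(n))
    trajectory_chem = chemistry  # exposed via spec consumers when needed
    _ = trajectory_chem
    return SyntheticEnsemble(
        trajectory=trajectory,
        fragments=frag_map,
        frame_features=frame_features,
        frame_records=frame_records,
        regime_labels=regime_idx,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# umbrella-sampling fixtures
# ---------------------------------------------------------------------------


@dataclass
class PotentialSpec:
    """Analytic 1-D potential (kJ/mol over nm) to sample windows from.

    forms: "harmonic" (params kappa, center), "double_well" (params a, b:
    U = a (x^2 - b^2)^2, barrier a*b^4 between wells at +-b), "table"
    (params xi, u arrays, linearly interpolated).
    """

    form: str
    params: dict = field(default_factory=dict)
    xi_range: tuple[float, float] = (-1.0, 1.0)

    def evaluate(self, xi) -> np.ndarray:
        x = np.asarray(xi, dtype=float)
        if self.form == "harmonic":
            kappa = float(self.params["kappa"])
            c = float(self.params.get("center", 0.0))
            return 0.5 * kappa * (x - c) ** 2
        if self.form == "double_well":
            a = float(self.params["a"])
            b = float(self.params["b"])
            return a * (x**2 - b**2) ** 2
        if self.form == "table":
            return np.interp(x, np.asarray(self.params["xi"]), np.asarray(self.params["u"]))
        raise ValueError(f"unknown potential form {self.form!r}")


def gen_us_windows(
    potential: PotentialSpec,
    centers: Sequence[float],
    force_constants: float | Sequence[float],
    n_per_window: int,
    temperature: float = 310.0,
    seed: int | None = None,
    grid_points: int = 10_000,
) -> list[UmbrellaWindow]:
    """Exact biased-Boltzmann samples for each umbrella window.

    Samples are drawn by inverse-CDF on a fine grid over the declared
    range from p_i(x) proportional to exp(-beta [U(x) + k_i/2 (x-c_i)^2]),
    so closed-form distributional checks apply (for harmonic U the sample
    variance is kT / (kappa + k_i)).
    """
    if seed is None:
        raise ValueError("gen_us_windows requires an explicit seed")
    lo, hi = potential.xi_range
    if not np.all((np.asarray(centers) >= lo) & (np.asarray(centers) <= hi)):
        raise ValueError("window centers must lie inside the potential range")
    ks = np.broadcast_to(np.asarray(force_constants, dtype=float), (len(centers),))
    rng = np.random.default_rng(seed)
    beta = 1.0 / (KB * temperature)
    x = np.linspace(lo, hi, grid_points)
    u = potential.evaluate(x)
    if not np.all(np.isfinite(u)):
        raise ValueError("potential is not finite over the sampled range")
    windows = []
    for c, k in zip(centers, ks):
        logp = -beta * (u + 0.5 * k * (x - c) ** 2)
        logp -= logp.max()
        p = np.exp(logp)
        z = np.trapezoid(p, x)
        if not np.isfinite(z) or z <= 0:
            raise ValueError(f"unnormalizable biased density at center {c}")
        cdf = np.concatenate(([0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(x)))) / z
        cdf[-1] = 1.0
        samples = np.interp(rng.random(n_per_window), cdf, x)
        windows.append(UmbrellaWindow(center=float(c), force_constant=float(k), samples=samples))
    return windows


def gen_dose_response(
    ic50: float,
    h: float,
    doses: Sequence[float],
    n_replicates: int,
    noise_sigma: float,
    seed: int | None = None,
    drug: str = "synthetic",
    branch: str = "outward",
) -> DoseResponseTable:
    """Hill-curve fractional block plus Gaussian noise, truncated to the
    [-0.05, 1.05] guard band."""
    import pandas as pd

    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if seed is None:
        raise ValueError("gen_dose_response requires an explicit seed")
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        mu = hill(d, ic50, h)
        for r in range(n_replicates):
            b = float(np.clip(mu + rng.normal(0.0, noise_sigma), -0.05, 1.05))
            rows.append({"conc_uM": float(d), "block": b, "replicate_id": r})
    return DoseResponseTable(drug=drug, branch=branch, data=pd.DataFrame(rows))


@dataclass
class ScreenLibrary:
    molecules: list[Molecule]
    planted: dict[str, tuple[int, ...]]  # molecule id -> representative indices


def gen_screen_library(
    representatives: Sequence[RepresentativeModel],
    n_actives: int,
    n_decoys: int,
    placement_sigma: float = 0.3,
    seed: int | None = None,
    min_active: int = 2,
) -> ScreenLibrary:
    """Planted actives and geometry-scrambled decoys for retrieval tests.

    Each active picks at least ``min_active`` representatives and carries
    one conformer per picked model whose features sit within r_tol/2 of
    that model (Gaussian jitter, norm-clipped). Each decoy copies a
    model's feature-kind multiset but displaces every feature by 2.5-6
    tolerance radii in a random direction, destroying the internal
    geometry while keeping the kind composition screenable.
    """
    if not representatives:
        raise ValueError("need at least one representative model")
    if seed is None:
        raise ValueError("gen_screen_library requires an explicit seed")
    rng = np.random.default_rng(seed)
    n_models = len(representatives)
    molecules: list[Molecule] = []
    planted: dict[str, tuple[int, ...]] = {}

    def jitter_within(center: np.ndarray, r_tol: float) -> np.ndarray:
        v = rng.normal(0.0, placement_sigma, size=3)
        norm = np.linalg.norm(v)
        cap = 0.5 * r_tol
        if norm > cap:
            v *= 0.99 * cap / norm
        return center + v

    for i in range(n_actives):
        k = int(rng.integers(min_active, n_models + 1))
        chosen = tuple(sorted(rng.choice(n_models, size=k, replace=False)))
        conformers = []
        for m in chosen:
            feats = [
                f.moved(jitter_within(f.xyz, f.r_tol), None)
                for f in representatives[m].model.sorted_features()
            ]
            conformers.append(feats)
        mid = f"ACT{i:03d}"
        molecules.append(Molecule(molecule_id=mid, conformers=conformers, label="active"))
        planted[mid] = chosen

    for j in range(n_decoys):
        rep = representatives[j % n_models]
        feats = []
        for f in rep.model.sorted_features():
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            magnitude = f.r_tol * rng.uniform(2.5, 6.0)
            feats.append(f.moved(f.xyz + magnitude * u, None))
        mid = f"DEC{j:03d}"
        molecules.append(Molecule(molecule_id=mid, conformers=[feats], label="decoy"))
    return ScreenLibrary(molecules=molecules, planted=planted)
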