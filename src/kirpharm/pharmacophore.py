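"""Dynamic pharmacophore models and common-hits-approach (CHA) screening.

A per-frame pharmacophore model is the set of ligand features that
participate in at least one ligand-receptor interaction in that frame.
Frames whose models share the same feature kinds *and* the same involved
ligand atoms belong to one representative model; merging the per-frame
models over an MD ensemble yields a small family of representatives with
frame counts, the dominant one typically covering >95% of frames.

Screening matches each library conformer's feature points against every
representative by exhaustive kind-consistent assignment plus least-squares
rigid superposition; a molecule is a hit when it matches at least
``min_active`` representatives. The per-model geometric score is

    s_m = 1 - (mean pair distance after superposition) / r_tol

and the CHA score of a molecule is the sum of s_m over matched models, so
a molecule matching k models scores just below k. This scoring convention
reproduces the structure of published CHA hit lists, not any proprietary
tool's exact numbers.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .geometry import kabsch
from .perception import FeaturePoint, InteractionRecord

__all__ = [
    "PharmacophoreModel",
    "RepresentativeModel",
    "MatchResult",
    "ScreenHit",
    "Molecule",
    "build_frame_model",
    "merge_models",
    "match_model",
    "screen_library",
    "CommonHitsScreen",
    "representatives_to_json",
    "representatives_from_json",
    "load_feature_library_csv",
    "load_sdf_library",
    "hits_to_frame",
]

IdentityKey = tuple[tuple[str, tuple[int, ...]], ...]


def _feature_sort_key(f: FeaturePoint):
    return (f.kind, tuple(sorted(f.ligand_atom_ids)))


@dataclass(frozen=True)
class PharmacophoreModel:
    """An ordered set of feature points with a frame-independent identity.

    The identity key — the sorted multiset of (kind, involved ligand
    atoms) — decides which per-frame models merge into one representative.
    """

    features: tuple[FeaturePoint, ...]
    source_frame: int | None = None

    @property
    def is_empty(self) -> bool:
        return not self.features

    @property
    def identity_key(self) -> IdentityKey:
        return tuple(sorted(_feature_sort_key(f) for f in self.features))

    def sorted_features(self) -> tuple[FeaturePoint, ...]:
        return tuple(sorted(self.features, key=_feature_sort_key))

    def centers(self) -> np.ndarray:
        return np.array([f.xyz for f in self.sorted_features()])


@dataclass(frozen=True)
class RepresentativeModel:
    """A merged model: mean feature geometry plus its frame support."""

    model: PharmacophoreModel
    count: int
    frequency: float

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not 0 < self.frequency <= 1:
            raise ValueError("frequency must lie in (0, 1]")


@dataclass
class MatchResult:
    matched: bool
    score: float
    pairing: tuple[int, ...] | None  # model feature i -> conformer feature pairing[i]
    distances: np.ndarray | None

    def __post_init__(self) -> None:
        if self.matched:
            if self.pairing is None or self.distances is None:
                raise ValueError("matched result requires pairing and distances")


@dataclass
class ScreenHit:
    molecule_id: str
    name: str
    scores: dict[int, float]  # model index -> best score, matched models only
    n_models: int

    @property
    def n_active(self) -> int:
        return len(self.scores)

    @property
    def cha_score(self) -> float:
        return float(sum(self.scores.values()))


@dataclass
class Molecule:
    """A screening-library molecule as per-conformer feature points."""

    molecule_id: str
    conformers: list[list[FeaturePoint]]
    name: str = ""
    label: str = ""  # optional ground-truth tag from generators


class FrameMixError(ValueError):
    pass


def build_frame_model(
    frame_records: Sequence[InteractionRecord],
    frame_features: Sequence[FeaturePoint],
) -> PharmacophoreModel:
    """Pharmacophore model of one frame from its interactions.

    A feature enters the model when at least one record of the matching
    kind involves its ligand atoms; duplicates collapse. A frame with no
    interactions yields the empty-model sentinel, which the merging stage
    excludes from frequency statistics.
    """
    frames = {r.frame_index for r in frame_records}
    if len(frames) > 1:
        raise FrameMixError(f"records span multiple frames: {sorted(frames)}")
    source = frames.pop() if frames else None
    chosen: dict[tuple, FeaturePoint] = {}
    for feat in frame_features:
        for rec in frame_records:
            if rec.feature_kind == feat.kind and (rec.ligand_atom_ids & feat.ligand_atom_ids):
                chosen.setdefault(_feature_sort_key(feat), feat)
                break
    return PharmacophoreModel(
        features=tuple(chosen[k] for k in sorted(chosen)), source_frame=source
    )


def merge_models(models: Iterable[PharmacophoreModel]) -> list[RepresentativeModel]:
    """Merge per-frame models into representatives with frame counts.

    Models group by identity key; each group's representative carries the
    mean feature centers over its member frames. Empty-model sentinels are
    excluded from the denominator. Output is ordered by count descending,
    then identity key.
    """
    groups: dict[IdentityKey, list[PharmacophoreModel]] = {}
    n_non_empty = 0
    for m in models:
        if m.is_empty:
            continue
        n_non_empty += 1
        groups.setdefault(m.identity_key, []).append(m)
    if n_non_empty == 0:
        raise ValueError("no non-empty models to merge")
    reps: list[RepresentativeModel] = []
    for key, members in groups.items():
        stack = np.stack([m.centers() for m in members])  # (n, k, 3)
        mean_centers = stack.mean(axis=0)
        template = members[0].sorted_features()
        merged_feats = []
        for f, c in zip(template, mean_centers):
            direction = f.direction
            if direction is not None:
                dirs = []
                for m in members:
                    for g in m.sorted_features():
                        if _feature_sort_key(g) == _feature_sort_key(f) and g.direction is not None:
                            dirs.append(g.direction)
                v = np.mean(np.array(dirs), axis=0)
                n = np.linalg.norm(v)
                direction = tuple(v / n) if n > 0 else None
            merged_feats.append(f.moved(c, None if direction is None else np.asarray(direction)))
        reps.append(
            RepresentativeModel(
                model=PharmacophoreModel(features=tuple(merged_feats)),
                count=len(members),
                frequency=len(members) / n_non_empty,
            )
        )
    reps.sort(key=lambda r: (-r.count, r.model.identity_key))
    return reps


def _assignments(model_feats, conf_feats):
    """Yield injective kind-consistent assignments model -> conformer.

    Each yielded value maps model feature position -> conformer feature
    index, enumerated in deterministic lexicographic order.
    """
    by_kind: dict[str, list[int]] = {}
    for j, f in enumerate(conf_feats):
        by_kind.setdefault(f.kind, []).append(j)
    kinds: dict[str, list[int]] = {}
    for i, f in enumerate(model_feats):
        kinds.setdefault(f.kind, []).append(i)
    per_kind_choices = []
    for kind, positions in sorted(kinds.items()):
        pool = by_kind.get(kind, [])
        if len(pool) < len(positions):
            return
        per_kind_choices.append(
            (positions, list(itertools.permutations(pool, len(positions))))
        )
    for combo in itertools.product(*(c for _, c in per_kind_choices)):
        assignment = [0] * len(model_feats)
        for (positions, _), picks in zip(per_kind_choices, combo):
            for i, j in zip(positions, picks):
                assignment[i] = j
        yield tuple(assignment)


def match_model(
    model: PharmacophoreModel,
    conformer_features: Sequence[FeaturePoint],
    r_tol: float | None = None,
) -> MatchResult:
    """Best geometric match of a model onto one conformer's features.

    All injective kind-consistent assignments are enumerated (models carry
    few features, typically 2-4); each is scored after least-squares rigid
    superposition of the model's feature centers onto the assigned
    conformer features. The match succeeds when some assignment puts every
    pair within the tolerance radius; score = 1 - mean distance / r_tol.
    Ties break on the lexicographically smallest pairing.
    """
    if model.is_empty:
        raise ValueError("cannot match an empty model")
    feats = model.sorted_features()
    if len(feats) > 6:
        raise ValueError("exhaustive assignment supports at most 6 model features")
    tol = float(r_tol) if r_tol is not None else float(feats[0].r_tol)
    if not conformer_features:
        return MatchResult(matched=False, score=0.0, pairing=None, distances=None)
    M = np.array([f.xyz for f in feats])
    C = np.array([f.xyz for f in conformer_features])
    best: tuple[float, tuple[int, ...], np.ndarray] | None = None
    for assignment in _assignments(feats, conformer_features) or ():
        target = C[list(assignment)]
        R, t = kabsch(M, target)
        moved = M @ R.T + t
        d = np.linalg.norm(moved - target, axis=1)
        if np.any(d > tol):
            continue
        score = 1.0 - float(d.mean()) / tol
        if best is None or score > best[0] or (score == best[0] and assignment < best[1]):
            best = (score, assignment, d)
    if best is None:
        return MatchResult(matched=False, score=0.0, pairing=None, distances=None)
    return MatchResult(matched=True, score=best[0], pairing=best[1], distances=best[2])


def screen_library(
    representatives: Sequence[RepresentativeModel],
    library: Iterable[Molecule],
    min_active: int = 2,
    r_tol: float | None = None,
    max_conformers: int = 200,
) -> list[ScreenHit]:
    """Common-hits screen of a conformer library against representatives.

    For each molecule, s_m is the best score over its conformers for model
    m; molecules matching >= ``min_active`` models enter the hit list,
    ranked by CHA score (sum of matched s_m) descending.
    """
    representatives = list(representatives)
    if not representatives:
        raise ValueError("need at least one representative model")
    if min_active > len(representatives):
        raise ValueError(
            f"min_active={min_active} exceeds the {len(representatives)} models"
        )
    hits: list[ScreenHit] = []
    for mol in library:
        if len(mol.conformers) > max_conformers:
            raise ValueError(
                f"molecule {mol.molecule_id} has {len(mol.conformers)} conformers "
                f"(max {max_conformers})"
            )
        scores: dict[int, float] = {}
        for m, rep in enumerate(representatives):
            best = None
            for conf in mol.conformers:
                res = match_model(rep.model, conf, r_tol=r_tol)
                if res.matched and (best is None or res.score > best):
                    best = res.score
            if best is not None:
                scores[m] = best
        if len(scores) >= min_active:
            hits.append(
                ScreenHit(
                    molecule_id=mol.molecule_id,
                    name=mol.name,
                    scores=scores,
                    n_models=len(representatives),
                )
            )
    hits.sort(key=lambda h: (-h.cha_score, h.molecule_id))
    return hits


class CommonHitsScreen(BaseEstimator):
    """Estimator wrapper: fit merges per-frame models, screen ranks a library.

    Parameters
    ----------
    min_active:
        Minimum number of representative models a molecule must match to
        count as a hit (the published filter keeps >=2 of 5).
    r_tol:
        Override tolerance radius in Angstrom; None uses each feature's own.
    max_conformers:
        Upper bound on conformers per molecule (200, the conformer-library
        generation cap).
    """

    def __init__(self, min_active: int = 2, r_tol: float | None = None, max_conformers: int = 200):
        self.min_active = min_active
        self.r_tol = r_tol
        self.max_conformers = max_conformers

    def fit(self, models: Iterable[PharmacophoreModel], y=None):
        models = list(models)
        self.representatives_ = merge_models(models)
        self.n_frames_ = sum(1 for m in models if not m.is_empty)
        self.n_models_ = len(self.representatives_)
        return self

    def screen(self, library: Iterable[Molecule]) -> list[ScreenHit]:
        if not hasattr(self, "representatives_"):
            raise RuntimeError("fit before screening")
        return screen_library(
            self.representatives_,
            library,
            min_active=self.min_active,
            r_tol=self.r_tol,
            max_conformers=self.max_conformers,
        )


# ---------------------------------------------------------------------------
# serialization and library I/O
# ---------------------------------------------------------------------------


def representatives_to_json(reps: Sequence[RepresentativeModel]) -> str:
    doc = []
    for rep in reps:
        doc.append(
            {
                "count": rep.count,
                "frequency": rep.frequency,
                "features": [
                    {
                        "kind": f.kind,
                        "center": list(f.center),
                        "r_tol": f.r_tol,
                        "ligand_atom_ids": sorted(f.ligand_atom_ids),
                        "direction": None if f.direction is None else list(f.direction),
                    }
                    for f in rep.model.sorted_features()
                ],
            }
        )
    return json.dumps(doc, indent=1)


def representatives_from_json(text: str) -> list[RepresentativeModel]:
    doc = json.loads(text)
    reps = []
    for entry in doc:
        feats = tuple(
            FeaturePoint(
                kind=f["kind"],
                center=tuple(f["center"]),
                ligand_atom_ids=frozenset(f["ligand_atom_ids"]),
                direction=None if f.get("direction") is None else tuple(f["direction"]),
                r_tol=f.get("r_tol", 1.5),
            )
            for f in entry["features"]
        )
        reps.append(
            RepresentativeModel(
                model=PharmacophoreModel(features=feats),
                count=int(entry["count"]),
                frequency=float(entry["frequency"]),
            )
        )
    return reps


def load_feature_library_csv(source, r_tol: float = 1.5) -> list[Molecule]:
    """Read a tabular feature-point library.

    Columns: molecule_id, conformer, kind, x, y, z (A), optional name.
    """
    import pandas as pd

    df = pd.read_csv(source)
    required = {"molecule_id", "conformer", "kind", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"library file missing columns: {sorted(missing)}")
    mols: list[Molecule] = []
    for mid, group in df.groupby("molecule_id", sort=True):
        name = str(group["name"].iloc[0]) if "name" in group else ""
        conformers = []
        for _, conf in group.groupby("conformer", sort=True):
            feats = [
                FeaturePoint(
                    kind=row.kind,
                    center=(row.x, row.y, row.z),
                    ligand_atom_ids=frozenset([i + 1]),
                    r_tol=r_tol,
                )
                for i, row in enumerate(conf.itertuples())
            ]
            conformers.append(feats)
        mols.append(Molecule(molecule_id=str(mid), conformers=conformers, name=name))
    return mols


_RDKIT_FAMILY_TO_KIND = {
    "Hydrophobe": "H",
    "LumpedHydrophobe": "H",
    "Aromatic": "AR",
    "Donor": "HBD",
    "Acceptor": "HBA",
    "PosIonizable": "PI",
}


def load_sdf_library(path, r_tol: float = 1.5) -> list[Molecule]:
    """Perceive feature points from a 3-D SDF conformer library via RDKit.

    Successive records sharing a molecule name (or _Name property) are
    treated as conformers of one molecule.
    """
    from rdkit import Chem, RDConfig
    from rdkit.Chem import ChemicalFeatures
    import os

    factory = ChemicalFeatures.BuildFeatureFactory(
        os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
    )
    grouped: dict[str, Molecule] = {}
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        feats = []
        for f in factory.GetFeaturesForMol(mol):
            kind = _RDKIT_FAMILY_TO_KIND.get(f.GetFamily())
            if kind is None:
                continue
            pos = f.GetPos()
            feats.append(
                FeaturePoint(
                    kind=kind,
                    center=(pos.x, pos.y, pos.z),
                    ligand_atom_ids=frozenset(a + 1 for a in f.GetAtomIds()),
                    r_tol=r_tol,
                )
            )
        entry = grouped.setdefault(name, Molecule(molecule_id=name, conformers=[], name=name))
        entry.conformers.append(feats)
    return list(grouped.values())


def hits_to_frame(hits: Sequence[ScreenHit]):
    """Hit list as a DataFrame shaped like a published CHA ranking."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "molecule_id": h.molecule_id,
                "name": h.name,
                "cha_score": h.cha_score,
                "n_active": h.n_active,
                "n_models": h.n_models,
            }
            for h in hits
        ],
        columns=["molecule_id", "name", "cha_score", "n_active", "n_models"],
    )
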