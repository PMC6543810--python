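import itertools
import warnings

import numpy as np
import pytest

from kirpharm.perception import FeaturePoint, InteractionRecord
from kirpharm.pharmacophore import (
    CommonHitsScreen,
    FrameMixError,
    Molecule,
    PharmacophoreModel,
    build_frame_model,
    hits_to_frame,
    load_feature_library_csv,
    match_model,
    merge_models,
    representatives_from_json,
    representatives_to_json,
    screen_library,
)
from kirpharm.synthetic import default_ensemble_spec, gen_feature_trajectory, gen_screen_library
from tests.conftest import random_rotation


def feat(kind, center, ids, r_tol=1.5):
    return FeaturePoint(
        kind=kind, center=tuple(map(float, center)), ligand_atom_ids=frozenset(ids), r_tol=r_tol
    )


def rec(kind, ids, frame=0):
    return InteractionRecord(
        frame_index=frame,
        kind=kind,
        ligand_atom_ids=frozenset(ids),
        fragment_name="unassigned",
        partner=("LEU", 57, "A"),
        distance=3.5,
    )


F_H1 = feat("H", (0, 0, 0), {1, 2})
F_H2 = feat("H", (5, 0, 0), {3, 4})
F_D = feat("HBD", (8, 1, 0), {5})


class TestBuildFrameModel:
    def test_interacting_features_enter_the_model(self):
        records = [rec("H", {1}), rec("H", {3}), rec("HB_donor", {5})]
        model = build_frame_model(records, [F_H1, F_H2, F_D])
        assert len(model.features) == 3
        assert [k for k, _ in model.identity_key] == ["H", "H", "HBD"]

    def test_no_records_yield_empty_sentinel(self):
        model = build_frame_model([], [F_H1, F_H2])
        assert model.is_empty

    def test_duplicate_records_collapse(self):
        model = build_frame_model([rec("H", {1}), rec("H", {2})], [F_H1])
        assert len(model.features) == 1

    def test_kind_mismatch_keeps_feature_out(self):
        model = build_frame_model([rec("HB_donor", {1})], [F_H1])
        assert model.is_empty

    def test_mixed_frames_rejected(self):
        with pytest.raises(FrameMixError):
            build_frame_model([rec("H", {1}, frame=0), rec("H", {3}, frame=1)], [F_H1, F_H2])


class TestMergeModels:
    def _model(self, key_tag, jitter=0.0, rng=None):
        offset = 0.0 if rng is None else rng.normal(scale=jitter, size=3)
        feats = {
            "A": [feat("H", np.array([0, 0, 0]) + offset, {1})],
            "B": [feat("H", (0, 0, 0), {2})],
            "C": [feat("HBA", (1, 1, 1), {3})],
        }[key_tag]
        return PharmacophoreModel(features=tuple(feats))

    def test_grouping_counts_example(self):
        models = [self._model(t) for t in "AAAABC"]
        reps = merge_models(models)
        assert [r.count for r in reps] == [4, 1, 1]
        assert sum(r.count for r in reps) == 6
        assert sum(r.frequency for r in reps) == pytest.approx(1.0, abs=1e-9)

    def test_all_identical_gives_single_representative(self):
        reps = merge_models([self._model("A")] * 5)
        assert len(reps) == 1 and reps[0].frequency == 1.0

    def test_mean_centers_over_members(self):
        rng = np.random.default_rng(0)
        models = [self._model("A", jitter=0.4, rng=rng) for _ in range(200)]
        reps = merge_models(models)
        assert np.allclose(reps[0].model.centers()[0], 0.0, atol=0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_grouping_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tags = rng.choice(list("ABC"), size=60)
        models = [self._model(t) for t in tags]
        reps = merge_models(models)
        # oracle: plain dict grouping on the identity key
        expected: dict = {}
        for m in models:
            expected[m.identity_key] = expected.get(m.identity_key, 0) + 1
        assert {r.model.identity_key: r.count for r in reps} == expected
        assert sum(r.count for r in reps) == len(models)
        counts = [r.count for r in reps]
        assert counts == sorted(counts, reverse=True)

    def test_empty_models_excluded_from_denominator(self):
        models = [self._model("A"), PharmacophoreModel(features=()), self._model("A")]
        reps = merge_models(models)
        assert reps[0].count == 2 and reps[0].frequency == 1.0

    def test_default_ensemble_reproduces_five_model_family(self):
        ens = gen_feature_trajectory(default_ensemble_spec(n_frames=5000), seed=42)
        reps = merge_models(ens.frame_models())
        assert len(reps) == 5
        assert reps[0].frequency > 0.95


def oracle_match(model_feats, conf_feats, r_tol):
    """Independent exhaustive matcher: scipy superposition, itertools only."""
    from scipy.spatial.transform import Rotation

    by_kind = {}
    for j, f in enumerate(conf_feats):
        by_kind.setdefault(f.kind, []).append(j)
    kinds = {}
    for i, f in enumerate(model_feats):
        kinds.setdefault(f.kind, []).append(i)
    pools = []
    for kind, idx in sorted(kinds.items()):
        cands = list(itertools.permutations(by_kind.get(kind, []), len(idx)))
        if not cands:
            return False, 0.0
        pools.append((idx, cands))
    M = np.array([f.center for f in model_feats])
    C = np.array([f.center for f in conf_feats])
    best = None
    for combo in itertools.product(*(c for _, c in pools)):
        assignment = [0] * len(model_feats)
        for (idx, _), picks in zip(pools, combo):
            for i, j in zip(idx, picks):
                assignment[i] = j
        T = C[assignment]
        mu_m, mu_t = M.mean(axis=0), T.mean(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rot, _ = Rotation.align_vectors(T - mu_t, M - mu_m)
        moved = rot.apply(M - mu_m) + mu_t
        d = np.linalg.norm(moved - T, axis=1)
        if np.all(d <= r_tol):
            s = 1.0 - d.mean() / r_tol
            if best is None or s > best:
                best = s
    return (best is not None), (best or 0.0)


def random_instance(rng):
    kinds = rng.choice(["H", "AR", "HBD", "HBA", "PI"], size=rng.integers(2, 6))
    model = [
        feat(k, rng.normal(scale=3.0, size=3), {i + 1})
        for i, k in enumerate(kinds)
    ]
    # conformer: sometimes a jittered rigid copy, sometimes unrelated noise
    if rng.random() < 0.5:
        R = random_rotation(rng)
        t = rng.normal(scale=4.0, size=3)
        conf = [
            feat(f.kind, R @ np.asarray(f.center) + t + rng.normal(scale=0.6, size=3), {10 + i})
            for i, f in enumerate(model)
        ]
    else:
        conf = [
            feat(str(rng.choice(["H", "AR", "HBD", "HBA", "PI"])),
                 rng.normal(scale=3.0, size=3), {10 + i})
            for i in range(rng.integers(1, 7))
        ]
    return PharmacophoreModel(features=tuple(model)), conf


class TestMatchModel:
    def test_identity_match_scores_one(self):
        model = PharmacophoreModel(features=(F_H1, F_H2, F_D))
        res = match_model(model, [F_H1, F_H2, F_D])
        assert res.matched and res.score == pytest.approx(1.0, abs=1e-9)

    def test_rigid_rotation_invariance(self):
        model = PharmacophoreModel(features=(F_H1, F_H2, F_D))
        rng = np.random.default_rng(9)
        R = random_rotation(rng)
        t = np.array([2.0, 3.0, -1.0])
        conf = [feat(f.kind, R @ np.asarray(f.center) + t, {20 + i}) for i, f in enumerate(model.features)]
        res = match_model(model, conf)
        assert res.matched
        assert res.score == pytest.approx(1.0, abs=1e-6)

    def test_empty_conformer_is_unmatched_not_error(self):
        model = PharmacophoreModel(features=(F_H1,))
        res = match_model(model, [])
        assert not res.matched and res.score == 0.0

    def test_score_formula_on_matched_instances(self):
        rng = np.random.default_rng(3)
        found = 0
        for _ in range(200):
            model, conf = random_instance(rng)
            res = match_model(model, conf)
            if res.matched:
                found += 1
                assert np.all(res.distances <= 1.5 + 1e-12)
                assert res.score == pytest.approx(1.0 - res.distances.mean() / 1.5)
        assert found > 20

    def test_agrees_with_exhaustive_permutation_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(500):
            model, conf = random_instance(rng)
            res = match_model(model, conf)
            matched, score = oracle_match(model.sorted_features(), conf, r_tol=1.5)
            assert res.matched == matched
            assert res.score == pytest.approx(score, abs=1e-8)


class TestScreenLibrary:
    def _reps(self, small=False):
        ens = gen_feature_trajectory(default_ensemble_spec(n_frames=300), seed=5)
        return merge_models(ens.frame_models())

    def test_planted_active_sums_matched_scores(self):
        model_a = PharmacophoreModel(features=(F_H1, F_H2))
        model_b = PharmacophoreModel(features=(F_H1, F_H2, F_D))
        from kirpharm.pharmacophore import RepresentativeModel

        reps = [
            RepresentativeModel(model=model_b, count=3, frequency=0.75),
            RepresentativeModel(model=model_a, count=1, frequency=0.25),
        ]
        mol = Molecule(
            molecule_id="ACT000",
            conformers=[[F_H1, F_H2, F_D]],
        )
        hits = screen_library(reps, [mol], min_active=2)
        assert len(hits) == 1
        h = hits[0]
        assert h.n_active == 2
        assert h.cha_score == pytest.approx(sum(h.scores.values()))
        assert h.cha_score <= h.n_active

    def test_decoys_filtered_and_ranking_structure(self, representatives):
        lib = gen_screen_library(representatives, n_actives=8, n_decoys=30, seed=21)
        hits = screen_library(representatives, lib.molecules, min_active=2)
        ids = {h.molecule_id for h in hits}
        planted_ids = set(lib.planted)
        assert planted_ids <= ids
        for h in hits:
            assert 0 < h.cha_score <= h.n_active <= len(representatives)
        scores = [h.cha_score for h in hits]
        assert scores == sorted(scores, reverse=True)

    def test_raising_min_active_never_adds_molecules(self, representatives):
        lib = gen_screen_library(representatives, n_actives=6, n_decoys=10, seed=2)
        ids_by_min = [
            {h.molecule_id for h in screen_library(representatives, lib.molecules, min_active=k)}
            for k in (1, 2, 3)
        ]
        assert ids_by_min[2] <= ids_by_min[1] <= ids_by_min[0]

    def test_adding_conformers_never_decreases_scores(self, representatives):
        lib = gen_screen_library(representatives, n_actives=4, n_decoys=0, seed=8)
        mol = lib.molecules[0]
        partial = Molecule(molecule_id=mol.molecule_id, conformers=mol.conformers[:1])
        h_partial = screen_library(representatives, [partial], min_active=1)
        h_full = screen_library(representatives, [mol], min_active=1)
        s_partial = h_partial[0].scores if h_partial else {}
        s_full = h_full[0].scores
        for m, s in s_partial.items():
            assert s_full[m] >= s - 1e-12

    def test_min_active_above_model_count_rejected(self, representatives):
        with pytest.raises(ValueError, match="min_active"):
            screen_library(representatives, [], min_active=len(representatives) + 1)

    def test_conformer_cap_enforced(self, representatives):
        mol = Molecule(molecule_id="X", conformers=[[F_H1]] * 3)
        with pytest.raises(ValueError, match="conformers"):
            screen_library(representatives, [mol], min_active=1, max_conformers=2)

    def test_estimator_wrapper_and_hit_frame(self, small_ensemble):
        screen = CommonHitsScreen(min_active=2).fit(small_ensemble.frame_models())
        assert screen.n_models_ == 5
        lib = gen_screen_library(screen.representatives_, 3, 3, seed=4)
        frame = hits_to_frame(screen.screen(lib.molecules))
        assert list(frame.columns) == ["molecule_id", "name", "cha_score", "n_active", "n_models"]
        assert set(lib.planted) <= set(frame.molecule_id)


class TestSerializationAndLibraries:
    def test_representative_json_round_trip(self, representatives):
        back = representatives_from_json(representatives_to_json(representatives))
        assert len(back) == len(representatives)
        for a, b in zip(representatives, back):
            assert a.model.identity_key == b.model.identity_key
            assert a.count == b.count
            assert np.allclose(a.model.centers(), b.model.centers())

    def test_feature_library_csv_round_trip(self, tmp_path):
        import pandas as pd

        rows = [
            {"molecule_id": "M1", "conformer": 0, "kind": "H", "x": 0.0, "y": 0.0, "z": 0.0},
            {"molecule_id": "M1", "conformer": 0, "kind": "HBD", "x": 3.0, "y": 0.0, "z": 0.0},
            {"molecule_id": "M1", "conformer": 1, "kind": "H", "x": 0.1, "y": 0.0, "z": 0.0},
            {"molecule_id": "M2", "conformer": 0, "kind": "AR", "x": 1.0, "y": 2.0, "z": 3.0},
        ]
        path = tmp_path / "lib.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        mols = load_feature_library_csv(path)
        assert [m.molecule_id for m in mols] == ["M1", "M2"]
        assert len(mols[0].conformers) == 2
        assert mols[0].conformers[0][1].kind == "HBD"

    def test_sdf_library_perceives_aromatic_and_hydrophobic(self, tmp_path):
        from rdkit import Chem
        from rdkit.Chem import AllChem

        mol = Chem.AddHs(Chem.MolFromSmiles("Cc1ccccc1"))  # toluene
        AllChem.EmbedMolecule(mol, randomSeed=7)
        mol.SetProp("_Name", "toluene")
        path = tmp_path / "lib.sdf"
        with Chem.SDWriter(str(path)) as w:
            w.write(mol)
        from kirpharm.pharmacophore import load_sdf_library

        mols = load_sdf_library(path)
        assert len(mols) == 1
        kinds = {f.kind for f in mols[0].conformers[0]}
        assert "AR" in kinds
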