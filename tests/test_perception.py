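import numpy as np
import pytest

from kirpharm.perception import (
    LigandChemistry,
    PerceptionRules,
    detect_interactions,
    perceive_features,
    receptor_view,
)
from kirpharm.synthetic import _default_ligand, default_ensemble_spec, gen_feature_trajectory
from tests.conftest import random_rotation


def _hexagon(z=0.0):
    ang = np.linspace(0, 2 * np.pi, 7)[:-1]
    return {i + 1: np.array([1.39 * np.cos(a), 1.39 * np.sin(a), z]) for i, a in enumerate(ang)}


BENZENE_CHEM = LigandChemistry.from_config(
    {
        "bonds": [[1, 2], [2, 3], [3, 4], [4, 5], [5, 6], [6, 1]],
        "aromatic_atoms": [1, 2, 3, 4, 5, 6],
    }
)


class TestPerceiveFeatures:
    def test_benzene_yields_single_ar_at_centroid(self):
        pos = _hexagon()
        feats = perceive_features(pos, {i: "C" for i in pos}, BENZENE_CHEM)
        ar = [f for f in feats if f.kind == "AR"]
        assert len(ar) == 1
        assert np.allclose(ar[0].xyz, 0.0, atol=1e-9)
        assert abs(np.linalg.norm(ar[0].direction) - 1.0) < 1e-9
        # the six apolar ring carbons also cluster into one H feature
        assert sum(f.kind == "H" for f in feats) == 1

    def test_ring_perception_without_bonds_errors(self):
        chem = LigandChemistry(aromatic_atoms=frozenset({1, 2, 3}))
        pos = {i: np.zeros(3) + i for i in (1, 2, 3)}
        with pytest.raises(ValueError, match="bond"):
            perceive_features(pos, {i: "C" for i in pos}, chem)

    def test_thiazolidinedione_nh_gives_hbd_on_nitrogen(self):
        coords, elements, _frags, chem_cfg = _default_ligand()
        feats = perceive_features(coords, elements, LigandChemistry.from_config(chem_cfg))
        hbd = [f for f in feats if f.kind == "HBD"]
        assert len(hbd) == 1
        assert hbd[0].ligand_atom_ids == frozenset({18})
        assert np.allclose(hbd[0].xyz, coords[18])

    def test_single_apolar_carbon_is_one_h_feature_at_atom(self):
        chem = LigandChemistry(apolar_carbons=frozenset({5}))
        pos = {5: np.array([1.0, 2.0, 3.0])}
        feats = perceive_features(pos, {5: "C"}, chem)
        assert [f.kind for f in feats] == ["H"]
        assert np.allclose(feats[0].xyz, [1.0, 2.0, 3.0])

    def test_rigid_transform_covariance(self):
        coords, elements, _frags, chem_cfg = _default_ligand()
        chem = LigandChemistry.from_config(chem_cfg)
        feats = perceive_features(coords, elements, chem)
        rng = np.random.default_rng(5)
        R = random_rotation(rng)
        t = np.array([4.0, -1.0, 2.0])
        moved = {i: R @ p + t for i, p in coords.items()}
        feats2 = perceive_features(moved, elements, chem)
        assert len(feats2) == len(feats)
        for a, b in zip(feats, feats2):
            assert a.kind == b.kind and a.ligand_atom_ids == b.ligand_atom_ids
            assert np.allclose(R @ a.xyz + t, b.xyz, atol=1e-8)


class TestDetectInteractions:
    def _scene(self, seed, n_receptor=40):
        """Random apolar ligand atoms + typed receptor for oracle scans."""
        rng = np.random.default_rng(seed)
        lig_pos = {i + 1: rng.normal(scale=3.0, size=3) for i in range(6)}
        chem = LigandChemistry(
            apolar_carbons=frozenset(lig_pos),
            donors=frozenset({1}),
            pi_nitrogens=frozenset({2}),
        )
        feats = perceive_features(lig_pos, {i: "C" for i in lig_pos}, chem)
        from kirpharm.trajectory import AtomRecord, Trajectory

        residues = []
        names = [("CB", "C", "LEU"), ("O", "O", "GLY"), ("N", "N", "GLY"), ("OD1", "O", "ASP")]
        atoms, coords = [], []
        for k in range(n_receptor):
            name, el, resn = names[k % len(names)]
            atoms.append(
                AtomRecord(
                    atom_id=100 + k,
                    name=name,
                    element=el,
                    residue_name=resn,
                    residue_number=k + 1,
                    chain_id="A",
                )
            )
            coords.append(rng.normal(scale=5.0, size=3))
        traj = Trajectory(
            atoms=atoms, coords=np.array(coords)[None], times=np.array([0.0])
        )
        return lig_pos, feats, receptor_view(traj, 0), atoms, np.array(coords)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_pair_scan(self, seed):
        rules = PerceptionRules()
        lig_pos, feats, view, atoms, coords = self._scene(seed)
        records = detect_interactions(lig_pos, feats, view, rules)
        got = {
            (r.kind, tuple(sorted(r.ligand_atom_ids)), r.partner): round(r.distance, 9)
            for r in records
        }
        # independent nested-loop oracle over all (feature, receptor atom)
        expected = {}

        def note(kind, ids, partner, d):
            key = (kind, tuple(sorted(ids)), partner)
            if key not in expected or d < expected[key]:
                expected[key] = round(d, 9)

        for f in feats:
            for a, pos in zip(atoms, coords):
                partner = (a.residue_name, a.residue_number, a.chain_id)
                d = float(np.linalg.norm(np.asarray(f.center) - pos))
                if f.kind == "H" and a.name == "CB":
                    dm = min(
                        float(np.linalg.norm(lig_pos[i] - pos))
                        for i in f.ligand_atom_ids
                    )
                    if dm <= rules.h_cutoff:
                        note("H", f.ligand_atom_ids, partner, dm)
                elif f.kind == "HBD" and a.name in ("O", "OD1"):
                    if d <= rules.hb_distance:
                        note("HB_donor", f.ligand_atom_ids, partner, d)
                elif f.kind == "PI" and a.name == "OD1":
                    if d <= rules.pi_cutoff:
                        note("PI", f.ligand_atom_ids, partner, d)
        assert got == expected

    def test_hb_distance_cutoff_boundary(self):
        from kirpharm.trajectory import AtomRecord, Trajectory

        def receptor_at(x):
            atoms = [
                AtomRecord(
                    atom_id=50, name="O", element="O", residue_name="GLY",
                    residue_number=9, chain_id="A",
                )
            ]
            return receptor_view(
                Trajectory(atoms=atoms, coords=np.array([[[x, 0, 0]]]), times=np.zeros(1)),
                0,
            )

        chem = LigandChemistry(donors=frozenset({1}))
        pos = {1: np.zeros(3)}
        feats = perceive_features(pos, {1: "N"}, chem)
        close = detect_interactions(pos, feats, receptor_at(3.0))
        far = detect_interactions(pos, feats, receptor_at(4.2))
        assert [r.kind for r in close] == ["HB_donor"]
        assert close[0].distance == pytest.approx(3.0)
        assert far == []

    def test_bulk_lipid_never_appears_as_partner(self, small_ensemble):
        # the stub receptor contains a POPC-like residue; the receptor scope
        # must drop it while keeping protein and PIP2
        traj = small_ensemble.trajectory
        view = receptor_view(traj, 0)
        resnames = {p[0] for p in view.partners}
        assert "POP" not in resnames
        assert "PIP2" in resnames
        no_pip = receptor_view(traj, 0, include_pip2=False)
        assert all(p[0] != "PIP2" for p in no_pip.partners)

    def test_records_carry_fragment_assignment(self, small_ensemble):
        coords, elements, _frags, chem_cfg = _default_ligand()
        chem = LigandChemistry.from_config(chem_cfg)
        traj = small_ensemble.trajectory
        pos = traj.positions(0)
        feats = perceive_features(
            pos, {a.atom_id: a.element for a in traj.atoms if a.is_ligand}, chem
        )
        recs = detect_interactions(
            pos, feats, receptor_view(traj, 0), fragments=small_ensemble.fragments
        )
        assert recs, "stub binding site should produce interactions"
        assert {r.fragment_name for r in recs} <= {
            "RingA", "RingB", "RingC", "LinkerD", "LinkerE", "unassigned"
        }
        assert all(r.distance > 0 for r in recs)
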