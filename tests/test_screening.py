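"""Feature perception, geometric matching (vs a brute-force oracle), rule of five."""
import itertools
import math
from unittest import mock

import numpy as np
import pytest

import ppi_pharmscreen as pp
from ppi_pharmscreen import screening as sc
from ppi_pharmscreen import synthetic as syn
from ppi_pharmscreen.core import SmallMolecule
from ppi_pharmscreen.pharmacophore import ConstraintSpec, PharmacophoreFeature, PharmacophoreModel


def _benzene():
    coords = [(1.3905 * math.cos(a), 1.3905 * math.sin(a), 0.0)
              for a in np.linspace(0, 2 * math.pi, 6, endpoint=False)]
    bonds = [(0, 1, 2.0), (1, 2, 1.0), (2, 3, 2.0), (3, 4, 1.0), (4, 5, 2.0), (5, 0, 1.0)]
    return SmallMolecule(["C"] * 6, [0] * 6, bonds, [np.array(coords)], name="benzene")


def _glycine_zwitterion():
    # N+H3-CH2-COO-  with explicit hydrogens on the ammonium
    elements = ["N", "H", "H", "H", "C", "C", "O", "O"]
    charges = [1, 0, 0, 0, 0, 0, 0, -1]
    bonds = [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0), (0, 4, 1.0),
             (4, 5, 1.0), (5, 6, 2.0), (5, 7, 1.0)]
    coords = np.array([
        [0.0, 0.0, 0.0], [0.5, 0.8, 0.3], [0.5, -0.8, 0.3], [-0.9, 0.0, 0.5],
        [0.0, 0.0, -1.47], [1.2, 0.6, -2.2], [2.3, 0.5, -1.7], [1.1, 1.2, -3.3],
    ])
    return SmallMolecule(elements, charges, bonds, [coords], name="glycine-zwitterion")


def _piperazine_diprotonated():
    # six-membered ring, two opposing N+, explicit H on each nitrogen
    ring = [(1.46 * math.cos(a), 1.46 * math.sin(a), 0.0)
            for a in np.linspace(0, 2 * math.pi, 6, endpoint=False)]
    elements = ["N", "C", "C", "N", "C", "C", "H", "H", "H", "H"]
    charges = [1, 0, 0, 1, 0, 0, 0, 0, 0, 0]
    bonds = [(i, (i + 1) % 6, 1.0) for i in range(6)]
    bonds += [(0, 6, 1.0), (0, 7, 1.0), (3, 8, 1.0), (3, 9, 1.0)]
    coords = np.array(ring + [
        [ring[0][0] + 0.6, ring[0][1] + 0.6, 0.6], [ring[0][0] + 0.6, ring[0][1] - 0.6, -0.6],
        [ring[3][0] - 0.6, ring[3][1] + 0.6, 0.6], [ring[3][0] - 0.6, ring[3][1] - 0.6, -0.6],
    ])
    return SmallMolecule(elements, charges, bonds, [coords], name="piperazinium")


class TestPerception:
    def test_benzene_gives_exactly_one_aromatic_feature_at_centroid(self):
        feats = sc.perceive_features(_benzene())
        assert len(feats) == 1
        assert feats[0].ftype == "Aro"
        assert np.allclose(feats[0].position, [0, 0, 0], atol=1e-9)

    def test_glycine_zwitterion_features(self):
        mol = _glycine_zwitterion()
        feats = sc.perceive_features(mol)
        by_type = {}
        for f in feats:
            by_type.setdefault(f.ftype, []).append(f)
        assert len(by_type["Cat"]) == 1 and by_type["Cat"][0].member_atoms == {0}
        assert len(by_type["Ani"]) == 1
        assert np.allclose(by_type["Ani"][0].position,
                           0.5 * (mol.conformers[0][6] + mol.conformers[0][7]))
        assert "Don" in by_type and "Acc" in by_type
        assert "Aro" not in by_type and "Hyd" not in by_type
        # protonated ammonium keeps no lone pair: not an acceptor
        assert all(0 not in f.member_atoms for f in by_type["Acc"])

    def test_diprotonated_piperazine_has_two_cation_features(self):
        feats = sc.perceive_features(_piperazine_diprotonated())
        cats = [f for f in feats if f.ftype == "Cat"]
        assert len(cats) == 2
        assert {frozenset(f.member_atoms) for f in cats} == {frozenset({0}), frozenset({3})}
        assert not any(f.ftype == "Aro" for f in feats)  # saturated ring

    def test_conformer_index_out_of_range(self):
        with pytest.raises(IndexError):
            sc.perceive_features(_benzene(), conformer=1)


# --------------------------------------------------------------------------
# matching
# --------------------------------------------------------------------------

def _oracle_superpose(centers, positions):
    """Independent optimal superposition via scipy's rotation fitting."""
    from scipy.spatial.transform import Rotation
    c0 = centers - centers.mean(axis=0)
    p0 = positions - positions.mean(axis=0)
    rot, _ = Rotation.align_vectors(c0, p0)
    moved = rot.apply(p0) + centers.mean(axis=0)
    return moved, math.sqrt(((moved - centers) ** 2).sum(axis=1).mean())


def _oracle_matches(model, features, min_points=3):
    """Exhaustive enumeration over label subsets and injective assignments."""
    accepted = set()
    labels = model.labels
    for size in range(min_points, len(labels) + 1):
        for subset in itertools.combinations(labels, size):
            matched = set(subset)
            if not set(model.constraints.essential) <= matched:
                continue
            if not all(len(set(g) & matched) >= k for g, k in model.constraints.choice_groups):
                continue
            cands = [
                [i for i, f in enumerate(features) if f.ftype == model.feature(lab).ftype]
                for lab in subset
            ]
            centers = np.array([model.feature(lab).center for lab in subset])
            radii = np.array([model.feature(lab).radius for lab in subset])
            for combo in itertools.product(*cands):
                if len(set(combo)) != len(combo):
                    continue
                pos = np.array([features[i].position for i in combo])
                try:
                    moved, _ = _oracle_superpose(centers, pos)
                except Exception:
                    continue
                if np.all(np.linalg.norm(moved - centers, axis=1) <= radii + 1e-9):
                    accepted.add(frozenset(zip(subset, combo)))
    return accepted


def _random_model(rng, n_features):
    types = rng.choice(["Aro", "Hyd", "Ani", "Cat", "Don", "Acc"], size=n_features)
    centers = rng.uniform(-6, 6, size=(n_features, 3))
    feats = [PharmacophoreFeature(f"F{i + 1}", t, tuple(c), radius=float(rng.uniform(0.8, 1.6)))
             for i, (t, c) in enumerate(zip(types, centers))]
    cons = ConstraintSpec(essential=frozenset({"F1"}))
    return PharmacophoreModel("random", feats, cons)


def _random_features(rng, model, n_features):
    feats = []
    for i in range(n_features):
        if i < len(model.features) and rng.random() < 0.6:
            f = model.features[i]
            pos = np.asarray(f.center) + rng.normal(scale=0.6, size=3)
            ftype = f.ftype
        else:
            pos = rng.uniform(-6, 6, size=3)
            ftype = rng.choice(["Aro", "Hyd", "Ani", "Cat", "Don", "Acc"])
        feats.append(sc.LigandFeature(str(ftype), tuple(pos), frozenset({i})))
    return feats


class TestMatching:
    def test_identity_placement_gives_one_zero_rmsd_match(self, receptor_model):
        feats = [
            sc.LigandFeature("Ani", receptor_model.feature("F1").center, frozenset({0})),
            sc.LigandFeature("Aro", receptor_model.feature("F3").center, frozenset({1})),
            sc.LigandFeature("Hyd", receptor_model.feature("F5").center, frozenset({2})),
        ]
        matches = sc.match_model(receptor_model, feats)
        assert len(matches) == 1
        assert matches[0].fit_rmsd == pytest.approx(0.0, abs=1e-9)
        assert set(matches[0].assignment) == {"F1", "F3", "F5"}
        assert matches[0].satisfied

    def test_wrong_type_at_essential_point_blocks_matching(self, receptor_model):
        feats = [
            sc.LigandFeature("Ani", receptor_model.feature("F1").center, frozenset({0})),
            sc.LigandFeature("Aro", receptor_model.feature("F3").center, frozenset({1})),
            sc.LigandFeature("Aro", receptor_model.feature("F5").center, frozenset({2})),
        ]
        assert sc.match_model(receptor_model, feats) == []

    def test_matcher_equals_bruteforce_oracle_on_random_cases(self, rng):
        for case in range(12):
            model = _random_model(rng, int(rng.integers(4, 7)))
            features = _random_features(rng, model, int(rng.integers(3, 9)))
            got = {
                frozenset((lab, min(f.member_atoms)) for lab, f in m.assignment.items())
                for m in sc.match_model(model, features)
            }
            assert got == _oracle_matches(model, features), f"case {case}"

    def test_match_set_invariant_under_rigid_motion(self, receptor_model, rng):
        lig = syn.make_matching_ligand(receptor_model, ["F2", "F4", "F5"], seed=5)
        feats = sc.perceive_features(lig)
        base = sc.match_model(receptor_model, feats)
        from ppi_pharmscreen.synthetic import _random_rotation
        R = _random_rotation(rng)
        t = rng.uniform(-30, 30, size=3)
        moved = [sc.LigandFeature(f.ftype, tuple(R @ f.position_array + t), f.member_atoms)
                 for f in feats]
        rotated = sc.match_model(receptor_model, moved)
        assert len(base) == len(rotated) > 0
        for a, b in zip(base, rotated):
            assert set(a.assignment) == set(b.assignment)
            assert a.fit_rmsd == pytest.approx(b.fit_rmsd, abs=1e-6)

    @pytest.mark.parametrize("subset", [("F1", "F3", "F5"), ("F2", "F4", "F5"),
                                        ("F1", "F2", "F3", "F5")])
    def test_planted_ligands_match_and_essential_decoys_do_not(self, receptor_model, subset):
        lig = syn.make_matching_ligand(receptor_model, subset, seed=11)
        assert sc.match_model(receptor_model, sc.perceive_features(lig))
        decoy = syn.make_matching_ligand(receptor_model, subset, seed=11, drop=["F5"])
        assert sc.match_model(receptor_model, sc.perceive_features(decoy)) == []

    def test_small_constraint_sets_are_rejected_as_underdetermined(self):
        feats = [PharmacophoreFeature("F1", "Acc", (0.0, 0.0, 0.0)),
                 PharmacophoreFeature("F2", "Don", (3.0, 0.0, 0.0))]
        model = PharmacophoreModel("two-point", feats, ConstraintSpec())
        lig = [sc.LigandFeature("Acc", (0.0, 0.0, 0.0), frozenset({0})),
               sc.LigandFeature("Don", (3.0, 0.0, 0.0), frozenset({1}))]
        assert sc.match_model(model, lig) == []


# --------------------------------------------------------------------------
# rule of five
# --------------------------------------------------------------------------

def _ethanol():
    return SmallMolecule(["C", "C", "O"], [0, 0, 0], [(0, 1, 1.0), (1, 2, 1.0)],
                         [np.array([[0, 0, 0], [1.5, 0, 0], [2.2, 1.2, 0]])],
                         properties={"logP": -0.3}, name="ethanol")


def _alkane(n_carbons):
    bonds = [(i, i + 1, 1.0) for i in range(n_carbons - 1)]
    coords = np.array([[1.5 * i, 0.2 * (i % 2), 0.0] for i in range(n_carbons)])
    return SmallMolecule(["C"] * n_carbons, [0] * n_carbons, bonds, [coords],
                         properties={"logP": 2.0})


def _polyol_boundary():
    """Exactly 10 N+O and 5 N-H/O-H hydrogens: the inclusive rule boundary."""
    elements, charges, bonds, coords = [], [], [], []
    for i in range(10):
        c = len(elements)
        elements += ["C", "O"]
        charges += [0, 0]
        bonds.append((c, c + 1, 1.0))
        if i >= 5:
            elements.append("C")  # ether oxygen: no O-H
            charges.append(0)
            bonds.append((c + 1, c + 2, 1.0))
        coords = None
    n = len(elements)
    coords = np.array([[1.6 * i, 0.3 * (i % 3), 0.1 * i] for i in range(n)])
    return SmallMolecule(elements, charges, bonds, [coords], properties={"logP": 1.0})


class TestLipinski:
    def test_ethanol_passes_with_expected_descriptors(self):
        rep = sc.lipinski_filter(_ethanol())
        assert rep.mw == pytest.approx(46.07, abs=0.01)
        assert rep.hba == 1 and rep.hbd == 1
        assert rep.passes and rep.violated_rules == []

    def test_overweight_molecule_fails_only_mw(self):
        rep = sc.lipinski_filter(_alkane(42))  # C42H86, ~591 Da
        assert rep.mw > 500
        assert rep.violated_rules == ["MW"]
        assert not rep.passes

    def test_hba10_hbd5_boundary_passes(self):
        rep = sc.lipinski_filter(_polyol_boundary())
        assert rep.hba == 10 and rep.hbd == 5
        assert rep.mw < 500
        assert rep.passes

    def test_mw_exactly_500_fails_the_strict_rule(self):
        with mock.patch.object(sc, "molecular_weight", return_value=500.0):
            rep = sc.lipinski_filter(_ethanol())
        assert "MW" in rep.violated_rules

    def test_precomputed_logp_is_preferred_and_crippen_used_otherwise(self):
        mol = _ethanol()
        assert sc.lipinski_filter(mol).logp == pytest.approx(-0.3)
        mol.properties.pop("logP")
        est = sc.lipinski_filter(mol).logp
        assert -1.5 < est < 1.0  # Wildman-Crippen estimate for ethanol

    def test_adding_a_heteroatom_never_decreases_hba(self):
        base = _alkane(6)
        rep0 = sc.lipinski_filter(base)
        grown = SmallMolecule(base.elements + ["O"], base.formal_charges + [0],
                              base.bonds + [(5, 6, 1.0)],
                              [np.vstack([base.conformers[0], [[9.0, 0.0, 0.0]]])],
                              properties={"logP": 2.0})
        assert sc.lipinski_filter(grown).hba >= rep0.hba
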