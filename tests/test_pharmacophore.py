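"""Pharmacophore model construction, subset enumeration and matching."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from dynappi.pharmacophore import (
    ConformerFeatures,
    Feature,
    PharmacophoreModel,
    SubsetQuery,
    assign_ligand_features,
    build_sxip_model,
    enumerate_subsets,
    match_conformer,
    screen_library,
)
from dynappi.synthetic import plant_conformer_library


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_min_rmsd(query_feats, points):
    """Enumerate every kind-compatible injection and superpose each with
    scipy's align_vectors (independent of the package's Kabsch)."""
    q = np.array([f.center for f in query_feats])
    p = np.array([f.center for f in points])
    best = None
    for perm in itertools.permutations(range(len(points)), len(query_feats)):
        if any(query_feats[i].kind != points[j].kind for i, j in enumerate(perm)):
            continue
        moving = p[list(perm)]
        mq = q - q.mean(axis=0)
        mp = moving - moving.mean(axis=0)
        rot, rssd = Rotation.align_vectors(mq, mp)
        rmsd = math.sqrt(rssd**2 / len(query_feats))
        if best is None or rmsd < best:
            best = rmsd
    return best


def make_conf(points, mol="m", conf="c"):
    return ConformerFeatures(
        molecule_id=mol,
        conformer_id=conf,
        points=tuple(
            Feature(kind=k, center=tuple(c), label=f"p{i}") for i, (k, c) in enumerate(points)
        ),
    )


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

class TestBuildModel:
    def test_sxip_preset_feature_count_and_kinds(self, sxip_model):
        assert len(sxip_model) == 8
        assert sxip_model.kind_histogram() == {"acceptor": 3, "donor": 2, "hydrophobic": 3}

    def test_chemically_corrected_swaps_backbone_assignments(self, sxip_peptide):
        model = build_sxip_model(sxip_peptide, chemically_corrected=True)
        assert model.kind_histogram() == {"acceptor": 4, "donor": 1, "hydrophobic": 3}

    def test_centers_are_atom_centroids(self, sxip_peptide, sxip_model):
        # independent centroid oracle: average the named atoms by hand
        ens = sxip_peptide
        pro_ring = np.mean(
            [ens.coords[0, ens.atom_index("P", 5480, a)] for a in ("CB", "CG", "CD")], axis=0
        )
        feat = next(f for f in sxip_model.features if f.label == "Pro5480:ring")
        np.testing.assert_allclose(feat.center, pro_ring, atol=1e-12)

    def test_empty_preset_rejected(self, sxip_peptide):
        with pytest.raises(ValueError, match="empty preset"):
            build_sxip_model(sxip_peptide, preset=[])

    def test_missing_atom_named_in_error(self, sxip_peptide):
        bad = [("X", 5477, "SER", ("XX9",), "acceptor")]
        with pytest.raises(KeyError, match="5477:XX9"):
            build_sxip_model(sxip_peptide, preset=bad)

    def test_direction_must_be_unit(self):
        with pytest.raises(ValueError, match="unit"):
            Feature(kind="donor", center=(0, 0, 0), direction=(0, 0, 2.0))


# ---------------------------------------------------------------------------
# subset enumeration
# ---------------------------------------------------------------------------

class TestEnumerateSubsets:
    @pytest.mark.parametrize(
        "n_feats,sizes,expected",
        [(8, {5, 6, 7}, 92), (8, {8}, 1), (4, {5}, 0), (8, {3}, 56)],
    )
    def test_counts(self, n_feats, sizes, expected):
        feats = [Feature(kind="donor", center=(i, 0, 0), label=f"f{i}") for i in range(n_feats)]
        model = PharmacophoreModel(features=tuple(feats))
        assert len(enumerate_subsets(model, sizes)) == expected

    def test_size_below_three_rejected(self, sxip_model):
        with pytest.raises(ValueError):
            enumerate_subsets(sxip_model, {2})

    def test_constraint_hook_filters(self, sxip_model):
        queries = enumerate_subsets(sxip_model, {5}, constraint=lambda idx: 0 in idx)
        assert len(queries) == math.comb(7, 4)
        assert all(0 in q.indices for q in queries)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(n=st.integers(3, 12), sizes=st.sets(st.integers(3, 12), min_size=1, max_size=4))
    def test_count_matches_binomial_sum(self, n, sizes):
        feats = [Feature(kind="acceptor", center=(i, 0, 0), label=f"f{i}") for i in range(n)]
        model = PharmacophoreModel(features=tuple(feats))
        expected = sum(math.comb(n, s) for s in sizes if s <= n)
        assert len(enumerate_subsets(model, sizes)) == expected

    def test_lexicographic_order_no_duplicates(self, sxip_model):
        queries = enumerate_subsets(sxip_model, {5, 6})
        idx = [q.indices for q in queries]
        assert len(set(idx)) == len(idx)
        by_size = {5: [i for i in idx if len(i) == 5], 6: [i for i in idx if len(i) == 6]}
        for size, block in by_size.items():
            assert block == sorted(block)


# ---------------------------------------------------------------------------
# ligand feature assignment
# ---------------------------------------------------------------------------

def _mol_from_molblock(block):
    from rdkit import Chem

    mol = Chem.MolFromMolBlock(block, removeHs=False)
    assert mol is not None
    return mol


METHANE = """
     RDKit          3D

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.1000    0.2000    0.3000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
"""

WATER = """
     RDKit          3D

  1  0  0  0  0  0  0  0  0  0999 V2000
    1.5000   -0.5000    2.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
M  END
"""


class TestAssignLigandFeatures:
    def test_methane_is_one_hydrophobic(self):
        conf = assign_ligand_features(_mol_from_molblock(METHANE), molecule_id="ch4")
        kinds = [p.kind for p in conf.points]
        assert kinds == ["hydrophobic"]
        np.testing.assert_allclose(conf.points[0].center, (0.1, 0.2, 0.3), atol=1e-4)

    def test_water_is_donor_and_acceptor_at_oxygen(self):
        conf = assign_ligand_features(_mol_from_molblock(WATER), molecule_id="h2o")
        kinds = sorted(p.kind for p in conf.points)
        assert "acceptor" in kinds and "donor" in kinds
        for p in conf.points:
            np.testing.assert_allclose(p.center, (1.5, -0.5, 2.0), atol=1e-4)

    def test_centroids_match_coordinate_average_oracle(self):
        # ethane-like: the hydrophobic features must sit on atom centroids
        from rdkit import Chem
        from rdkit.Chem import AllChem

        mol = Chem.AddHs(Chem.MolFromSmiles("CC"))
        AllChem.EmbedMolecule(mol, randomSeed=7)
        conf = assign_ligand_features(mol, molecule_id="eth")
        pos = mol.GetConformer().GetPositions()
        for p in conf.points:
            atom_idx = [int(s) for s in p.label.split(":")[1].split("+")]
            np.testing.assert_allclose(p.center, pos[atom_idx].mean(axis=0), atol=1e-9)

    def test_bad_smarts_rejected_at_load(self):
        with pytest.raises(ValueError, match="SMARTS"):
            assign_ligand_features(
                _mol_from_molblock(METHANE), rules=[("donor", "[[[")], molecule_id="x"
            )

    def test_molecule_without_coordinates_rejected(self):
        from rdkit import Chem

        with pytest.raises(ValueError, match="coordinates"):
            assign_ligand_features(Chem.MolFromSmiles("CCO"), molecule_id="x")


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

class TestMatchConformer:
    def _identity_case(self, sxip_model, size=5):
        query = enumerate_subsets(sxip_model, {size})[0]
        pts = [(f.kind, f.center) for f in query.features]
        return query, make_conf(pts)

    def test_identical_points_match_at_zero(self, sxip_model):
        query, conf = self._identity_case(sxip_model)
        m = match_conformer(query, conf, rmsd_max=0.5)
        assert m is not None
        assert m.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, sxip_model, rng):
        query, conf = self._identity_case(sxip_model, size=6)
        R = Rotation.random(random_state=4).as_matrix()
        t = rng.uniform(-20, 20, 3)
        moved = make_conf([(p.kind, tuple(R @ np.array(p.center) + t)) for p in conf.points])
        m = match_conformer(query, moved, rmsd_max=0.5)
        assert m is not None
        assert m.rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.det(m.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_cutoff_is_strict(self):
        # plant a configuration whose minimal rmsd is exactly ~0.51 A
        q = [("donor", (0, 0, 0)), ("donor", (3, 0, 0)), ("acceptor", (0, 3, 0))]
        query_model = PharmacophoreModel(
            features=tuple(Feature(kind=k, center=c, label=f"f{i}") for i, (k, c) in enumerate(q))
        )
        query = SubsetQuery(model=query_model, indices=(0, 1, 2))
        conf = make_conf(q)
        m0 = match_conformer(query, conf, rmsd_max=1.0)
        assert m0.rmsd == pytest.approx(0.0, abs=1e-9)
        # oracle-calibrated jitter: verify via the exhaustive oracle, then cutoff
        jit = [("donor", (0.3, 0.4, 0.2)), ("donor", (3, -0.3, 0.1)), ("acceptor", (-0.2, 3.4, 0))]
        conf_j = make_conf(jit)
        expect = oracle_min_rmsd(query.features, conf_j.points)
        m = match_conformer(query, conf_j, rmsd_max=10.0)
        assert m.rmsd == pytest.approx(expect, abs=1e-6)
        assert match_conformer(query, conf_j, rmsd_max=expect - 1e-6) is None

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_min_rmsd_equals_exhaustive_oracle(self, sxip_model, seed):
        rng = np.random.default_rng(seed)
        query = enumerate_subsets(sxip_model, {5})[seed]
        base = np.array([f.center for f in sxip_model.features])
        kinds = [f.kind for f in sxip_model.features]
        pts = base + rng.normal(scale=0.3, size=base.shape)
        conf = make_conf(list(zip(kinds, map(tuple, pts))))
        m = match_conformer(query, conf, rmsd_max=100.0)
        expect = oracle_min_rmsd(query.features, conf.points)
        assert m.rmsd == pytest.approx(expect, abs=1e-6)

    def test_no_kind_compatible_injection_returns_none(self, sxip_model):
        query = enumerate_subsets(sxip_model, {5})[0]
        pts = [("hydrophobic", (i * 1.0, 0, 0)) for i in range(8)]
        assert match_conformer(query, make_conf(pts), rmsd_max=100.0) is None

    def test_query_size_cap(self):
        feats = tuple(
            Feature(kind="donor", center=(i, 0, 0), label=f"f{i}") for i in range(13)
        )
        model = PharmacophoreModel(features=feats)
        query = SubsetQuery(model=model, indices=tuple(range(13)))
        conf = make_conf([("donor", (i, 0, 0)) for i in range(13)])
        with pytest.raises(ValueError, match="cap"):
            match_conformer(query, conf, rmsd_max=1.0)


# ---------------------------------------------------------------------------
# library screening
# ---------------------------------------------------------------------------

class TestScreenLibrary:
    def test_dedup_keeps_best_conformer(self, sxip_model):
        q = enumerate_subsets(sxip_model, {5})[0]
        base = [(f.kind, f.center) for f in q.features]
        good = make_conf(base, mol="molA", conf="c1")
        worse_pts = [(k, (c[0] + 0.2, c[1], c[2])) for k, c in base[:1]] + base[1:]
        worse = make_conf(worse_pts, mol="molA", conf="c2")
        hits = screen_library([worse, good], sxip_model, sizes=[5], rmsd_max=0.5)
        assert len(hits) == 1
        assert hits.iloc[0]["conformer_id"] == "c1"

    def test_empty_library_gives_empty_table(self, sxip_model):
        hits = screen_library([], sxip_model, sizes=[5], rmsd_max=0.5)
        assert len(hits) == 0
        assert list(hits.columns) == [
            "molecule_id", "conformer_id", "query_size", "query_indices", "rmsd_A",
        ]

    def test_planted_recovery_and_zero_decoy_acceptance(self, sxip_model):
        library, truth = plant_conformer_library(
            sxip_model, n_hits=6, n_decoys=12, jitter_sigma=0.05, seed=42
        )
        hits = screen_library(library, sxip_model, sizes=[6, 7], rmsd_max=0.5)
        reported = set(hits["molecule_id"])
        planted = set(truth.loc[truth["is_hit"], "molecule_id"])
        assert reported == planted
        assert (hits["rmsd_A"] <= 0.5).all()
        assert hits["molecule_id"].is_unique
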