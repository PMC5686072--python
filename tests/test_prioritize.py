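"""Properties, consensus scoring, Pareto ranking and selection filters."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dynappi.prioritize import (
    CompoundRecord,
    PoseSet,
    ScoreMatrix,
    consensus_top,
    ligand_efficiency,
    lipinski_profile,
    monoisotopic_mass,
    pareto_rank,
    parse_formula,
    pose_consistency,
    run_selection,
    solubility_filter,
)
from dynappi.synthetic import make_score_matrix


# ---------------------------------------------------------------------------
# monoisotopic mass
# ---------------------------------------------------------------------------

class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("C16H23N3O2", 289.18),  # tetrazole lead scaffold
            ("C18H25NO3", 303.18),  # Cbz-protected intermediate
        ],
    )
    def test_printed_formulas_at_two_decimals(self, formula, expected):
        assert round(monoisotopic_mass(formula), 2) == expected

    def test_water_by_hand(self):
        # 2 x 1.00782503207 + 15.9949146196 summed by hand
        assert monoisotopic_mass({"H": 2, "O": 1}) == pytest.approx(18.0105646837, abs=5e-5)

    def test_rdkit_cross_check(self):
        from rdkit.Chem.Descriptors import ExactMolWt
        from rdkit import Chem

        mol = Chem.MolFromSmiles("OCC(=O)NC")  # C3H7NO2
        assert monoisotopic_mass("C3H7NO2") == pytest.approx(ExactMolWt(mol), abs=1e-3)

    def test_unknown_element_named(self):
        with pytest.raises(KeyError, match="Zz"):
            monoisotopic_mass({"Zz": 1})

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        a=st.dictionaries(st.sampled_from(["C", "H", "N"]), st.integers(0, 50), max_size=3),
        b=st.dictionaries(st.sampled_from(["O", "S", "P"]), st.integers(0, 50), max_size=3),
    )
    def test_additivity_over_disjoint_formulas(self, a, b):
        merged = {**a, **b}
        assert monoisotopic_mass(merged) == pytest.approx(
            monoisotopic_mass(a) + monoisotopic_mass(b), rel=1e-12, abs=1e-12
        )

    def test_formula_parser(self):
        assert parse_formula("C18H25NO3") == {"C": 18, "H": 25, "N": 1, "O": 3}
        with pytest.raises(ValueError):
            parse_formula("C18H25NO3!")


# ---------------------------------------------------------------------------
# ligand efficiency / Lipinski / solubility
# ---------------------------------------------------------------------------

class TestSimpleProperties:
    def test_ligand_efficiency_values(self):
        assert ligand_efficiency(60.0, 20) == pytest.approx(3.0)
        assert ligand_efficiency(0.0, 15) == 0.0
        with pytest.raises(ValueError):
            ligand_efficiency(10.0, 0)

    def test_ligand_efficiency_elementwise_oracle(self, rng):
        scores = rng.normal(50, 10, size=(20, 4))
        heavy = rng.integers(10, 40, size=(20, 1))
        out = ligand_efficiency(scores, heavy)
        # brute-force division oracle
        for i in range(20):
            for j in range(4):
                assert out[i, j] == pytest.approx(scores[i, j] / heavy[i, 0])

    def test_ligand_efficiency_monotone_in_score(self):
        assert ligand_efficiency(61.0, 20) > ligand_efficiency(60.0, 20)

    @pytest.mark.parametrize(
        "props,violations",
        [
            (dict(mw=289.4, logp=2.0, hbd=1, hba=5), 0),
            (dict(mw=600.0, logp=2.0, hbd=1, hba=5), 1),
            (dict(mw=500.0, logp=5.0, hbd=5, hba=10), 0),  # boundary passes
            (dict(mw=600.0, logp=6.0, hbd=6, hba=11), 4),
        ],
    )
    def test_lipinski_violation_counts(self, props, violations):
        rec = CompoundRecord(id="x", **props)
        assert lipinski_profile(rec)["violations"] == violations

    def test_lipinski_missing_property_listed(self):
        rec = CompoundRecord(id="x", mw=300.0, logp=2.0, hbd=1)
        with pytest.raises(ValueError, match="hba"):
            lipinski_profile(rec)

    def test_solubility_filter_boundary_inclusive(self):
        recs = [
            CompoundRecord(id="keep", solubility=1e-3),
            CompoundRecord(id="boundary", solubility=1e-4),
            CompoundRecord(id="drop", solubility=1e-5),
        ]
        kept = {r.id for r in solubility_filter(recs, 1e-4)}
        assert kept == {"keep", "boundary"}

    def test_solubility_missing_names_compound(self):
        with pytest.raises(ValueError, match="nosol"):
            solubility_filter([CompoundRecord(id="nosol")])


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def consensus_oracle(matrix, fraction):
    """Independent sort-and-intersect."""
    k = math.ceil(fraction * len(matrix.compounds))
    sets = []
    for j, col in enumerate(matrix.columns):
        pairs = sorted(
            zip(matrix.compounds, matrix.scores[:, j]),
            key=lambda p: (-p[1] if matrix.higher_is_better[j] else p[1], p[0]),
        )
        sets.append({cid for cid, _ in pairs[:k]})
    return set.intersection(*sets)


class TestConsensus:
    def test_single_column_top_fraction(self, rng):
        scores = rng.normal(size=(100, 1))
        m = ScoreMatrix([f"c{i}" for i in range(100)], ["s"], scores)
        top = consensus_top(m, 0.1)
        assert len(top) == 10
        best = np.argsort(-scores[:, 0])[:10]
        assert top == {f"c{i}" for i in best}

    def test_disjoint_top_sets_intersect_empty(self):
        scores = np.array([[1.0, 4.0], [2.0, 3.0], [3.0, 2.0], [4.0, 1.0]])
        m = ScoreMatrix(["a", "b", "c", "d"], ["s1", "s2"], scores)
        assert consensus_top(m, 0.25) == set()

    def test_matches_sort_and_intersect_oracle(self, rng):
        scores = rng.normal(size=(50, 4))
        m = ScoreMatrix(
            [f"c{i}" for i in range(50)], list("wxyz"), scores,
            higher_is_better=[True, False, True, False],
        )
        assert consensus_top(m, 0.3) == consensus_oracle(m, 0.3)

    def test_fraction_one_returns_everything(self, rng):
        scores = rng.normal(size=(17, 3))
        m = ScoreMatrix([f"c{i}" for i in range(17)], list("abc"), scores)
        assert consensus_top(m, 1.0) == set(m.compounds)


# ---------------------------------------------------------------------------
# Pareto
# ---------------------------------------------------------------------------

def pareto_oracle_fronts(X, directions):
    """O(n^2) dominance peeling, independent of the package implementation."""
    Y = X * np.array([1 if d == "max" else -1 for d in directions])
    n = len(Y)
    remaining = set(range(n))
    front = {}
    k = 1
    while remaining:
        nondom = []
        for i in remaining:
            dominated = False
            for j in remaining:
                if i == j:
                    continue
                if np.all(Y[j] >= Y[i]) and np.any(Y[j] > Y[i]):
                    dominated = True
                    break
            if not dominated:
                nondom.append(i)
        for i in nondom:
            front[i] = k
            remaining.discard(i)
        k += 1
    return front


class TestPareto:
    def test_single_compound_front_one(self):
        res = pareto_rank(np.array([[1.0, 2.0]]), ["max", "max"], ids=["only"])
        assert res[0].front == 1

    def test_direct_dominance(self):
        res = pareto_rank(
            np.array([[2.0, 2.0], [1.0, 1.0]]), ["max", "max"], ids=["A", "B"]
        )
        assert {r.id: r.front for r in res} == {"A": 1, "B": 2}

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_fronts_match_dominance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 4))
        dirs = ["max", "min", "max", "min"]
        res = pareto_rank(X, dirs)
        expect = pareto_oracle_fronts(X, dirs)
        assert {int(r.id): r.front for r in res} == expect

    def test_fronts_partition_contiguously(self, rng):
        X = rng.normal(size=(120, 3))
        res = pareto_rank(X, ["max", "max", "min"])
        fronts = sorted({r.front for r in res})
        assert fronts == list(range(1, max(fronts) + 1))
        assert len(res) == 120

    def test_front_one_stable_under_dominated_addition(self, rng):
        X = rng.normal(size=(40, 3))
        dirs = ["max"] * 3
        base_front1 = {r.id for r in pareto_rank(X, dirs) if r.front == 1}
        dominated = X.min(axis=0) - 1.0  # dominated by every point
        X2 = np.vstack([X, dominated])
        front1 = {
            r.id for r in pareto_rank(X2, dirs) if r.front == 1 and int(r.id) < 40
        }
        assert front1 == base_front1

    def test_direction_length_mismatch(self):
        with pytest.raises(ValueError):
            pareto_rank(np.ones((3, 2)), ["max"])


# ---------------------------------------------------------------------------
# pose consistency
# ---------------------------------------------------------------------------

class TestPoseConsistency:
    def test_identical_poses_zero(self, rng):
        pose = rng.normal(size=(1, 12, 3)).repeat(5, axis=0)
        mean, mat = pose_consistency(PoseSet("c", pose))
        assert mean == 0.0
        assert np.all(mat == 0)

    def test_uniform_translation_closed_form(self, rng):
        p0 = rng.normal(size=(9, 3))
        poses = np.stack([p0, p0 + np.array([1.0, 0, 0])])
        mean, _ = pose_consistency(PoseSet("c", poses))
        assert mean == pytest.approx(1.0, abs=1e-12)

    def test_mean_matches_all_pairs_oracle(self, rng):
        P = rng.normal(size=(5, 7, 3))
        mean, mat = pose_consistency(PoseSet("c", P))
        acc = []
        for i in range(5):
            for j in range(i + 1, 5):
                acc.append(np.sqrt(((P[i] - P[j]) ** 2).sum(axis=1).mean()))
        assert mean == pytest.approx(np.mean(acc), abs=1e-12)

    def test_single_pose_rejected(self, rng):
        with pytest.raises(ValueError):
            pose_consistency(PoseSet("c", rng.normal(size=(1, 5, 3))))


# ---------------------------------------------------------------------------
# staged funnel
# ---------------------------------------------------------------------------

def _uniform_records(ids):
    return [
        CompoundRecord(id=c, mw=300.0, heavy_atoms=20, hbd=1, hba=4, logp=2.0, solubility=1e-3)
        for c in ids
    ]


class TestRunSelection:
    def test_planted_best_ranked_first(self):
        order = [f"cmp{i:02d}" for i in range(12)]
        matrix, truth = make_score_matrix(order, n_conformations=4, noise_sd=0.5, seed=9)
        shortlist, audit = run_selection(
            _uniform_records(order), matrix, consensus_fraction=0.5, top_n=None,
        )
        assert shortlist.iloc[0]["id"] == order[0]
        stages = [a["stage"] for a in audit]
        assert stages == [
            "input", "consensus", "pareto", "solubility", "lipinski", "pose_consistency",
        ]

    def test_pass_all_thresholds_equals_pareto_order(self):
        order = [f"c{i}" for i in range(8)]
        matrix, _ = make_score_matrix(order, n_conformations=3, noise_sd=0.0, seed=2)
        shortlist, _ = run_selection(
            _uniform_records(order), matrix,
            consensus_fraction=1.0, top_n=None, min_solubility=None,
            max_lipinski_violations=None,
        )
        # identical properties: ordering is driven by consensus score alone
        assert shortlist["id"].tolist() == order
        assert shortlist["front"].tolist() == list(range(1, 9))

    def test_empty_input_empty_shortlist(self):
        matrix = ScoreMatrix([], [], np.zeros((0, 0)))
        shortlist, audit = run_selection([], matrix)
        assert len(shortlist) == 0
        assert all(a["n_out"] == 0 for a in audit)
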