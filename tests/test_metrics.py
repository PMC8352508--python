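import json
from fractions import Fraction

import numpy as np
import pytest

from decoykit.chem import Molecule
from decoykit.fingerprints import functional_fingerprint, tanimoto
from decoykit.fixtures import bundled_drug_molecules, make_separable_sets
from decoykit.metrics import (ave_bias, compile_report, doe_score,
                              doppelganger_scores, ml_bias_assessment,
                              write_report)
from decoykit.properties import PropertySet


def doe_oracle(actives, decoys):
    """Exact-rational brute-force DOE: threshold-enumerated ROC points,
    segment-wise |TPR - FPR| integration with Fraction arithmetic."""
    actives = np.asarray(actives, float)
    decoys = np.asarray(decoys, float)
    X = np.vstack([actives, decoys])
    mu, sd = X.mean(0), X.std(0)
    sd = np.where(sd <= 1e-12, 1.0, sd)
    za, zd = (actives - mu) / sd, (decoys - mu) / sd
    per_active = []
    for i in range(len(za)):
        pos = [round(float(np.linalg.norm(za[i] - za[j])), 9)
               for j in range(len(za)) if j != i]
        neg = [round(float(np.linalg.norm(za[i] - d)), 9) for d in zd]
        pts = [(Fraction(0), Fraction(0))]
        for t in sorted(set(pos + neg)):
            x = Fraction(sum(1 for d in neg if d <= t), len(neg))
            y = Fraction(sum(1 for d in pos if d <= t), len(pos))
            pts.append((x, y))
        area = Fraction(0)
        for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
            if x1 == x0:
                continue
            f0, f1 = y0 - x0, y1 - x1
            if f0 * f1 >= 0:
                area += (abs(f0) + abs(f1)) * (x1 - x0) / 2
            else:
                t = f0 / (f0 - f1)
                area += (x1 - x0) * (abs(f0) * t + abs(f1) * (1 - t)) / 2
        per_active.append(area)
    return float(sum(per_active) / len(per_active))


class TestDOE:
    def test_identical_populations_zero(self):
        pts = np.tile([1.0, 2.0, 3.0], (5, 1))
        assert doe_score(pts, pts[:4]) == 0.0

    def test_complete_separation_half(self):
        actives = np.zeros((5, 3))
        decoys = np.full((20, 3), 100.0 / np.sqrt(3))
        assert doe_score(actives, decoys) == pytest.approx(0.5, abs=1e-12)

    def test_hand_sized_instance_matches_oracle(self):
        actives = np.array([[0.0], [1.0], [4.0]])
        decoys = np.array([[0.5], [2.0], [3.0], [10.0]])
        assert doe_score(actives, decoys) == \
            pytest.approx(doe_oracle(actives, decoys), abs=1e-12)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            na, nd = rng.integers(2, 8), rng.integers(1, 15)
            k = rng.integers(1, 4)
            a = rng.integers(0, 4, size=(na, k)).astype(float)
            d = rng.integers(0, 4, size=(nd, k)).astype(float)
            assert doe_score(a, d) == pytest.approx(doe_oracle(a, d),
                                                    abs=1e-10)

    def test_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.standard_normal((5, 2))
            d = rng.standard_normal((10, 2))
            assert 0.0 <= doe_score(a, d) <= 0.5

    def test_invariant_under_affine_property_rescaling(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((6, 3))
        d = rng.standard_normal((12, 3))
        scale = np.array([100.0, 0.01, 7.0])
        shift = np.array([-5.0, 3.0, 0.0])
        assert doe_score(a, d) == pytest.approx(
            doe_score(a * scale + shift, d * scale + shift), abs=1e-10)

    def test_needs_two_actives(self):
        with pytest.raises(ValueError):
            doe_score(np.zeros((1, 2)), np.zeros((3, 2)))

    def test_curves_returned(self):
        a = np.random.default_rng(3).standard_normal((4, 2))
        d = np.random.default_rng(4).standard_normal((6, 2))
        doe, curves = doe_score(a, d, return_curves=True)
        assert len(curves) == 4
        for xs, ys in curves:
            assert xs[0] == ys[0] == 0.0 and xs[-1] == ys[-1] == 1.0


class TestDoppelganger:
    def test_identical_decoy_scores_one(self):
        actives = [Molecule.from_smiles("CCO"), Molecule.from_smiles("CCC")]
        res = doppelganger_scores([Molecule.from_smiles("CCO")], actives)
        assert res.max == 1.0

    def test_disjoint_environments_zero(self):
        actives = [Molecule.from_smiles("CCCCC")]
        res = doppelganger_scores([Molecule.from_smiles("O=S(=O)(O)O")],
                                  actives)
        assert res.per_decoy[0] == 0.0

    def test_toy_table_mean_and_max(self):
        actives = [Molecule.from_smiles(s) for s in ("CCO", "CCN", "c1ccccc1")]
        decoys = [Molecule.from_smiles(s) for s in ("CCOC", "CCCN")]
        table = [[tanimoto(functional_fingerprint(d),
                           functional_fingerprint(a)) for a in actives]
                 for d in decoys]
        expected = [max(row) for row in table]
        res = doppelganger_scores(decoys, actives)
        np.testing.assert_allclose(res.per_decoy, expected)
        assert res.mean == pytest.approx(np.mean(expected))
        assert res.max == pytest.approx(np.max(expected))

    def test_adding_decoy_never_decreases_max(self):
        actives = bundled_drug_molecules()[:5]
        decoys = bundled_drug_molecules()[5:12]
        prev = doppelganger_scores(decoys[:3], actives).max
        for n in range(4, len(decoys) + 1):
            cur = doppelganger_scores(decoys[:n], actives).max
            assert cur >= prev
            prev = cur


def ave_oracle(actives, decoys, n_folds, n_thresholds, seed):
    """Direct evaluation of the four H terms, fold by fold."""
    from sklearn.model_selection import StratifiedKFold

    X = np.vstack([actives, decoys])
    mu, sd = X.mean(0), X.std(0)
    sd = np.where(sd <= 1e-12, 1.0, sd)
    za = (np.asarray(actives, float) - mu) / sd
    zd = (np.asarray(decoys, float) - mu) / sd
    X = np.vstack([za, zd])
    y = np.concatenate([np.ones(len(za)), np.zeros(len(zd))])
    grid = np.linspace(0, 1, n_thresholds)

    def H(V, T):
        vals = []
        for v in V:
            dmin = min(np.linalg.norm(v - t) for t in T)
            dmin = dmin / (1 + dmin)
            vals.append(np.mean(dmin <= grid))
        return np.mean(vals)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    out = []
    for tr, va in skf.split(X, y):
        ta, td = X[tr][y[tr] == 1], X[tr][y[tr] == 0]
        vA, vD = X[va][y[va] == 1], X[va][y[va] == 0]
        out.append((H(vA, ta) - H(vA, td)) + (H(vD, td) - H(vD, ta)))
    return float(np.mean(out))


class TestAVE:
    def test_same_distribution_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((60, 3))
        d = rng.standard_normal((60, 3))
        assert abs(ave_bias(a, d, seed=0)) < 0.15

    def test_separated_clusters_strongly_positive(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((30, 2)) * 0.1
        d = rng.standard_normal((30, 2)) * 0.1 + 50.0
        assert ave_bias(a, d, seed=0) > 0.5

    def test_small_instance_matches_hand_evaluation(self):
        actives = np.array([[0.0], [0.1], [2.0], [2.1]])
        decoys = np.array([[5.0], [5.1], [9.0], [9.1]])
        got = ave_bias(actives, decoys, n_folds=2, n_thresholds=11, seed=3)
        expected = ave_oracle(actives, decoys, 2, 11, 3)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_range(self):
        rng = np.random.default_rng(2)
        for s in range(5):
            a = rng.standard_normal((20, 2))
            d = rng.standard_normal((20, 2)) + s
            assert -2.0 <= ave_bias(a, d, seed=s) <= 2.0


class TestMLBias:
    def test_subset_count_for_k3(self):
        rng = np.random.default_rng(0)
        a, d = rng.standard_normal((12, 3)), rng.standard_normal((12, 3))
        table = ml_bias_assessment(a, d, ("p1", "p2", "p3"),
                                   model_kind="1NN", folds=4, seed=0)
        assert len(table) == 2 ** 3 - 1

    def test_perfectly_separating_property_auc_one(self):
        rng = np.random.default_rng(1)
        a = np.column_stack([np.full(15, 10.0), rng.standard_normal(15)])
        d = np.column_stack([np.full(15, -10.0), rng.standard_normal(15)])
        table = ml_bias_assessment(a, d, ("sep", "noise"),
                                   model_kind="1NN", folds=5, seed=0)
        assert table[("sep",)] == 1.0
        assert table[("sep", "noise")] == 1.0

    def test_random_forest_kind_runs(self):
        rng = np.random.default_rng(2)
        a, d = rng.standard_normal((15, 2)), rng.standard_normal((15, 2)) + 3
        table = ml_bias_assessment(a, d, ("x", "y"), model_kind="RF",
                                   folds=3, seed=0)
        assert len(table) == 3
        assert table[("x", "y")] > 0.8

    def test_unknown_model_kind(self):
        with pytest.raises(ValueError):
            ml_bias_assessment(np.zeros((5, 1)), np.zeros((5, 1)), ("a",),
                               model_kind="SVM")


@pytest.fixture(scope="module")
def mini_pset():
    return PropertySet("mini3", ("mol_weight", "logp", "hbd"))


@pytest.fixture(scope="module")
def report(mini_pset):
    actives = bundled_drug_molecules()[:8]
    decoys = bundled_drug_molecules()[8:24]
    return compile_report("toy", actives, decoys, mini_pset,
                          folds=4, seed=0)


class TestReport:
    def test_fields_and_ranges(self, report):
        assert 0.0 <= report["doe_score"] <= 0.5
        assert 0.0 <= report["doppelganger_mean"] <= \
            report["doppelganger_max"] <= 1.0
        assert -2.0 <= report["ave"] <= 2.0
        assert report["metadata"]["property_set"] == "mini3"
        assert not report["errors"]

    def test_subset_table_row_count(self, report):
        k = 3
        total = sum(len(v) for v in report["subset_auc"].values())
        assert total == 2 * (2 ** k - 1)

    def test_byte_identical_under_seed(self, mini_pset, tmp_path):
        actives = bundled_drug_molecules()[:6]
        decoys = bundled_drug_molecules()[6:18]
        paths = []
        for i in range(2):
            r = compile_report("t", actives, decoys, mini_pset,
                               folds=3, seed=5, model_kinds=("1NN",))
            p = tmp_path / f"r{i}.json"
            write_report(r, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_metric_failure_recorded_not_raised(self, mini_pset):
        # a single active makes DOE undefined; report still emitted
        actives = bundled_drug_molecules()[:1]
        decoys = bundled_drug_molecules()[1:6]
        r = compile_report("bad", actives, decoys, mini_pset, folds=2,
                           seed=0, subset_table=False)
        assert r["doe_score"] is None
        assert "doe_score" in r["errors"]


class TestSeparableFixtures:
    def test_zero_separation_low_doe(self):
        a, d = make_separable_sets(20, 60, 3, separation=0.0, seed=0)
        assert doe_score(a, d) < 0.12

    def test_large_separation_doe_half(self):
        a, d = make_separable_sets(5, 20, 3, separation=100.0, seed=0)
        assert doe_score(a, d) == pytest.approx(0.5, abs=1e-9)

    def test_monotone_in_separation(self):
        vals = [doe_score(*make_separable_sets(10, 30, 2, s, seed=1))
                for s in (0.0, 2.0, 100.0)]
        assert vals[0] < vals[1] < vals[2]
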