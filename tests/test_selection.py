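import numpy as np
import pytest

from decoykit.chem import Molecule, element_counts
from decoykit.fingerprints import functional_fingerprint
from decoykit.fixtures import bundled_drug_molecules
from decoykit.selection import (LadsScorer, ScoredCandidate, SelectionConfig,
                                build_decoy_set, filter_candidates,
                                greedy_select, lads_score)


class TestLads:
    def test_no_shared_environment_zero(self):
        actives = [Molecule.from_smiles("CCCCCC"),
                   Molecule.from_smiles("CCCCC")]
        decoy = Molecule.from_smiles("O=S(=O)(O)O")
        abits = set()
        for a in actives:
            abits |= functional_fingerprint(a).bits
        dbits = functional_fingerprint(decoy).bits
        assert not (abits & dbits)  # precondition: truly disjoint
        assert lads_score(decoy, actives) == 0.0

    def test_identical_to_active_maximal_in_pool(self):
        actives = bundled_drug_molecules()[:3]
        pool = bundled_drug_molecules()[3:10] + [actives[0]]
        scorer = LadsScorer(actives)
        scores = [scorer.score(c) for c in pool]
        assert np.argmax(scores) == len(pool) - 1

    def test_matches_documented_formula_on_toy_set(self):
        actives = [Molecule.from_smiles(s)
                   for s in ("CCO", "CCN", "CCC")]
        decoy = Molecule.from_smiles("CCOC")
        # independent recomputation from bit sets
        afps = [functional_fingerprint(a).bits for a in actives]
        dbits = functional_fingerprint(decoy).bits
        expected = sum(sum(1 for f in afps if b in f)
                       for b in dbits) / (len(dbits) * len(actives))
        assert lads_score(decoy, actives) == pytest.approx(expected)

    def test_deterministic(self):
        actives = bundled_drug_molecules()[:4]
        d = bundled_drug_molecules()[10]
        assert lads_score(d, actives) == lads_score(d, actives)


def _mols_of_sizes(sizes):
    return [Molecule.from_smiles("C" * s) for s in sizes]


class TestFilter:
    def test_no_relaxation_when_strict_pool_sufficient(self):
        active = Molecule.from_smiles("CCCCC")
        actives = [active]
        # alkane candidates: same heavy atom count, low similarity to active
        cands = _mols_of_sizes([5] * 12 + [7] * 5)
        cfg = SelectionConfig(min_pool=3, decoys_per_active=2,
                              initial_max_doppelganger=1.0)
        res = filter_candidates(cands, active, actives, cfg)
        assert not res.relaxed
        assert all(element_counts(c).total == 5 for c in res.candidates)

    def test_degenerate_identical_candidates_relax_with_warning(self):
        active = Molecule.from_smiles("CCO")
        cands = [Molecule.from_smiles("CCO") for _ in range(5)]
        cfg = SelectionConfig(min_pool=3, decoys_per_active=2)
        with pytest.warns(UserWarning):
            res = filter_candidates(cands, active, [active], cfg)
        assert res.relaxed
        assert len(res.candidates) >= 3

    def test_schedule_matches_manual_trace(self):
        """Alternating relaxation: atom-diff first, then doppelganger."""
        active = Molecule.from_smiles("CCCCC")
        # 2 exact-size candidates, 2 at +/-1 atom, 2 at +/-2 atoms; all
        # alkanes so doppelganger vs the single active is high and the
        # doppelganger axis must also relax
        cands = _mols_of_sizes([5, 5, 6, 4, 7, 3])
        cfg = SelectionConfig(min_pool=6, decoys_per_active=1,
                              initial_max_doppelganger=1.0)
        res = filter_candidates(cands, active, [active], cfg)
        # manual simulation: hd=0 -> 2; hd=1 -> 4; (dopp step, no change)
        # hd=2 -> 6 survivors
        hds = [t[0] for t in res.trace]
        ns = [t[2] for t in res.trace]
        assert ns[0] == 2 and ns[-1] == 6
        assert res.final_hac_diff == 2
        assert hds == sorted(hds)

    def test_insufficient_candidates_returns_all_with_warning(self):
        active = Molecule.from_smiles("CCCCC")
        cands = _mols_of_sizes([5, 5])
        cfg = SelectionConfig(min_pool=100, decoys_per_active=2,
                              initial_max_doppelganger=1.0)
        with pytest.warns(UserWarning):
            res = filter_candidates(cands, active, [active], cfg)
        assert len(res.candidates) == 2

    def test_empty_input(self):
        active = Molecule.from_smiles("CCCCC")
        res = filter_candidates([], active, [active])
        assert res.candidates == []


def _scored(smiles, combined):
    # split the combined score across its two parts
    return ScoredCandidate(Molecule.from_smiles(smiles),
                           prop_diff=combined / 2, lads=combined / 2,
                           doppelganger=0.1)


class TestGreedySelect:
    def test_smallest_combined_scores_win(self):
        cands = [_scored("CCCCC", 0.1), _scored("CCCCO", 0.5),
                 _scored("CCCCN", 0.3)]
        chosen = greedy_select(cands, 2)
        assert [c.molecule.canonical_smiles for c in chosen] == \
            ["CCCCC", "CCCCN"]

    def test_ties_break_by_canonical_smiles(self):
        cands = [_scored("CCO", 0.2), _scored("CCN", 0.2),
                 _scored("CCC", 0.2)]
        chosen = greedy_select(cands, 2)
        assert [c.molecule.canonical_smiles for c in chosen] == \
            ["CCC", "CCN"]

    def test_invariant_to_input_order(self):
        cands = [_scored(s, v) for s, v in
                 [("CCO", 0.4), ("CCN", 0.1), ("CCC", 0.9), ("CCF", 0.2)]]
        a = greedy_select(cands, 3)
        b = greedy_select(cands[::-1], 3)
        assert [c.molecule.canonical_smiles for c in a] == \
            [c.molecule.canonical_smiles for c in b]

    def test_n_equals_pool_identity(self):
        cands = [_scored("CCO", 0.4), _scored("CCN", 0.1)]
        assert len(greedy_select(cands, 2)) == 2

    def test_undersized_pool_warns(self):
        with pytest.warns(UserWarning):
            out = greedy_select([_scored("CCO", 0.1)], 5)
        assert len(out) == 1

    def test_combined_is_sum_of_parts(self):
        c = ScoredCandidate(Molecule.from_smiles("CCO"), 0.25, 0.5, 0.0)
        assert c.combined == pytest.approx(0.75)


@pytest.fixture(scope="module")
def small_cfg():
    return SelectionConfig(candidates_per_active=40, min_pool=10,
                           decoys_per_active=5, property_set="dude6")


class TestBuildDecoySet:
    def test_two_actives_five_each(self, trained_model, fixture_library,
                                   small_cfg):
        actives = [fixture_library[0], fixture_library[1]]
        ds = build_decoy_set(actives, trained_model, small_cfg, seed=4)
        mols = ds.all_molecules()
        assert len(mols) == 10
        from decoykit.chem import check_valence
        assert all(check_valence(m)[0] for m in mols)

    def test_seed_reproducible(self, trained_model, fixture_library,
                               small_cfg):
        actives = [fixture_library[0]]
        d1 = build_decoy_set(actives, trained_model, small_cfg, seed=7)
        d2 = build_decoy_set(actives, trained_model, small_cfg, seed=7)
        assert [m.canonical_smiles for m in d1.all_molecules()] == \
            [m.canonical_smiles for m in d2.all_molecules()]

    def test_report_accounting(self, trained_model, fixture_library,
                               small_cfg):
        actives = [fixture_library[5]]
        ds = build_decoy_set(actives, trained_model, small_cfg, seed=1)
        entry = ds.report["per_active"][actives[0].canonical_smiles]
        assert entry["generated"] + entry["failures"] == \
            small_cfg.candidates_per_active
        assert entry["unique"] + entry["duplicates"] <= entry["generated"]
        assert entry["selected"] <= small_cfg.decoys_per_active

    def test_final_decoys_respect_recorded_doppelganger_threshold(
            self, trained_model, fixture_library, small_cfg):
        actives = [fixture_library[0]]
        ds = build_decoy_set(actives, trained_model, small_cfg, seed=2)
        key = actives[0].canonical_smiles
        thr = ds.report["per_active"][key]["final_thresholds"]
        for c in ds.decoys[key]:
            assert c.doppelganger <= thr["max_doppelganger"] + 1e-9
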