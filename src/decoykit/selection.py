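"""Candidate filtering and greedy final-decoy selection.

Raw generated candidates for an active are deduplicated, filtered by an
iterative relaxation over heavy-atom-count difference and doppelganger
score until a minimum pool survives, then the final decoys are picked
greedily by the smallest sum of normalised property difference and LADS
score.  The LADS (latent actives in decoy set) score penalises decoys whose
functional-fingerprint environments are prevalent among the actives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem import Molecule, element_counts
from .fingerprints import functional_fingerprint, tanimoto
from .metrics import doppelganger_scores
from .properties import (PropertyNormalizer, get_property_set,
                         property_matrix)

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    """Candidate budget, filtering schedule and final-set size."""

    candidates_per_active: int = 1000
    min_pool: int = 100
    decoys_per_active: int = 30
    property_set: str = "dekois8"
    initial_max_hac_diff: int = 0
    initial_max_doppelganger: float = 0.25
    hac_step: int = 1
    doppelganger_step: float = 0.05

    def __post_init__(self):
        if self.min_pool < self.decoys_per_active:
            raise ValueError("min_pool must be >= decoys_per_active")
        if self.initial_max_doppelganger <= 0 or self.doppelganger_step <= 0:
            raise ValueError("doppelganger thresholds must be positive")


@dataclass(frozen=True)
class ScoredCandidate:
    """A candidate with its selection scores; combined = prop_diff + lads."""

    molecule: Molecule
    prop_diff: float
    lads: float
    doppelganger: float

    @property
    def combined(self) -> float:
        return self.prop_diff + self.lads


class LadsScorer:
    """Latent-actives-in-decoy-set penalty.

    For a decoy with functional-fingerprint bit set ``F_d``, the score is
    the mean, over bits in ``F_d``, of the fraction of actives whose
    fingerprint contains that bit::

        LADS(d) = (1/|F_d|) * sum_{f in F_d} n_actives(f) / N_actives

    A decoy sharing no environment with any active scores 0; one built
    entirely from environments common to all actives scores 1.  This is the
    weighted-occurrence form of the latent-active penalty used in
    property-matched decoy pipelines.
    """

    def __init__(self, actives):
        if not len(actives):
            raise ValueError("need at least one active")
        self.n_actives = len(actives)
        self.bit_counts: dict[int, int] = {}
        for a in actives:
            for b in functional_fingerprint(a).bits:
                self.bit_counts[b] = self.bit_counts.get(b, 0) + 1

    def score(self, decoy: Molecule) -> float:
        bits = functional_fingerprint(decoy).bits
        if not bits:
            return 0.0
        s = sum(self.bit_counts.get(b, 0) for b in bits)
        return s / (len(bits) * self.n_actives)


def lads_score(decoy: Molecule, actives) -> float:
    """Convenience wrapper around :class:`LadsScorer` for a single decoy."""
    return LadsScorer(actives).score(decoy)


@dataclass
class FilterResult:
    candidates: list
    trace: list = field(default_factory=list)  # (hac_diff, max_dopp, n_kept)
    final_hac_diff: int = 0
    final_max_doppelganger: float = 0.0
    relaxed: bool = False


def filter_candidates(candidates, active: Molecule, actives,
                      config: SelectionConfig | None = None) -> FilterResult:
    """Iteratively relax thresholds until at least ``min_pool`` survive.

    Starts at the strictest level (heavy-atom difference
    ``initial_max_hac_diff``, doppelganger ``initial_max_doppelganger``) and
    alternately widens the atom-count allowance and the doppelganger
    threshold, logging each level.  If even fully relaxed thresholds cannot
    reach the minimum pool, all candidates are returned with a warning.
    """
    config = config or SelectionConfig()
    candidates = list(candidates)
    if not candidates:
        return FilterResult([], [], config.initial_max_hac_diff,
                            config.initial_max_doppelganger)
    target_hac = element_counts(active).total
    hac_diff = np.array([abs(element_counts(c).total - target_hac)
                         for c in candidates])
    dopp = doppelganger_scores(candidates, actives).per_decoy

    hd = config.initial_max_hac_diff
    dp = config.initial_max_doppelganger
    trace = []
    relax_atom_next = True
    while True:
        mask = (hac_diff <= hd) & (dopp <= dp + 1e-12)
        n = int(mask.sum())
        if not trace and n == 0:
            warnings.warn("no candidates survive the strictest thresholds; "
                          "relaxing iteratively")
        trace.append((hd, round(dp, 6), n))
        if n >= min(config.min_pool, len(candidates)):
            if n < config.min_pool:
                warnings.warn(
                    f"only {n} candidates available (< min_pool "
                    f"{config.min_pool}); returning all survivors")
            kept = [c for c, m in zip(candidates, mask) if m]
            return FilterResult(kept, trace, hd, dp,
                                relaxed=len(trace) > 1)
        if hd >= hac_diff.max() and dp >= 1.0 - 1e-9:
            warnings.warn("thresholds fully relaxed; returning all "
                          f"{len(candidates)} candidates")
            return FilterResult(candidates, trace, hd, dp, relaxed=True)
        if relax_atom_next:
            hd += config.hac_step
        else:
            dp += config.doppelganger_step
        relax_atom_next = not relax_atom_next


def greedy_select(scored, n: int):
    """The ``n`` candidates with smallest combined score.

    Ties break by canonical SMILES, so the selection is deterministic and
    invariant to input ordering.
    """
    scored = sorted(scored, key=lambda c: (c.combined,
                                           c.molecule.canonical_smiles))
    if len(scored) < n:
        warnings.warn(f"only {len(scored)} candidates for n={n}")
    return scored[:n]


@dataclass
class DecoySet:
    """Final decoys per active plus a provenance report."""

    decoys: dict  # active canonical SMILES -> list of ScoredCandidate
    report: dict

    def all_molecules(self):
        return [c.molecule for lst in self.decoys.values() for c in lst]


def build_decoy_set(actives, model, config: SelectionConfig | None = None,
                    seed: int = 0) -> DecoySet:
    """End-to-end per-target pipeline: generate, deduplicate, filter,
    score, greedily select.

    Per-active failures are recorded in the report and the pipeline
    continues.  Deterministic under ``seed``.
    """
    config = config or SelectionConfig()
    actives = list(actives)
    pset = get_property_set(config.property_set)
    child_seeds = [int(s) for s in
                   np.random.SeedSequence(seed).generate_state(len(actives))
                   % (2 ** 31)]
    per_active_raw = {}
    report = {"config": {k: getattr(config, k) for k in
                         ("candidates_per_active", "min_pool",
                          "decoys_per_active", "property_set")},
              "seed": seed, "per_active": {}}

    active_smiles = {a.canonical_smiles for a in actives}
    all_candidates = []
    for a, s in zip(actives, child_seeds):
        entry = {"seed": s}
        cands, failures = model.sample(a, config.candidates_per_active,
                                       seed=s)
        entry["generated"] = len(cands)
        entry["failures"] = failures
        seen = {}
        for c in cands:
            key = c.canonical_smiles
            if key in active_smiles:
                continue
            if key not in seen:
                seen[key] = c
        entry["unique"] = len(seen)
        entry["duplicates"] = len(cands) - len(seen)
        per_active_raw[a.canonical_smiles] = list(seen.values())
        all_candidates.extend(seen.values())
        report["per_active"][a.canonical_smiles] = entry

    # per-target normalisation population: actives plus every candidate
    norm_pop = actives + all_candidates
    X = property_matrix(norm_pop, pset)
    finite = np.all(np.isfinite(X), axis=1)
    norm = PropertyNormalizer(
        population="target actives + generated candidates").fit(X[finite])

    decoys = {}
    scorer = LadsScorer(actives)
    for a in actives:
        key = a.canonical_smiles
        entry = report["per_active"][key]
        try:
            fr = filter_candidates(per_active_raw[key], a, actives, config)
            entry["filter_trace"] = fr.trace
            entry["final_thresholds"] = {
                "hac_diff": fr.final_hac_diff,
                "max_doppelganger": fr.final_max_doppelganger}
            za = norm.transform(property_matrix([a], pset))[0]
            dopp = doppelganger_scores(fr.candidates, actives).per_decoy \
                if fr.candidates else np.array([])
            scored = []
            for c, dp in zip(fr.candidates, dopp):
                zc = norm.transform(property_matrix([c], pset))[0]
                scored.append(ScoredCandidate(
                    c, float(np.linalg.norm(zc - za)), scorer.score(c),
                    float(dp)))
            chosen = greedy_select(scored, config.decoys_per_active)
            decoys[key] = chosen
            entry["selected"] = len(chosen)
        except Exception as exc:
            logger.error("active %s failed: %s", key, exc)
            entry["error"] = str(exc)
            decoys[key] = []
    return DecoySet(decoys, report)
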