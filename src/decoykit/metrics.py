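"""Bias assessment for active/decoy sets.

Four complementary views of residual bias between a target's actives and
its decoys:

* **DOE score** (deviation from optimal embedding): for each active, rank
  the other actives (positives) and all decoys (negatives) by ascending
  Euclidean distance in z-scored property space and build a ROC curve, with
  tied distances interpolated linearly as diagonal segments.  The score is
  the mean over actives of the absolute area between the curve and the
  diagonal.  0 means actives and decoys are perfectly embedded among each
  other; 0.5 means complete separation in property space.
* **doppelganger score**: per decoy, the maximum functional-fingerprint
  Tanimoto similarity to any active — the latent-active (false-negative)
  risk.  Reported per decoy with set mean and maximum.
* **AVE**: asymmetric validation embedding — a nearest-neighbour clumping
  statistic over cross-validation folds, in [-2, 2], ~0 when actives and
  decoys are drawn from one distribution.
* **ML bias**: AUC of 1-nearest-neighbour and random-forest classifiers
  trained on every non-empty subset of the property set under stratified
  cross-validation; AUC ~0.5 means the properties carry no class signal.

All metrics normalise properties by z-scoring on the union of the target's
actives and decoys, so each target is assessed in isolation.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .fingerprints import FUNCTIONAL_FLAVOR, functional_fingerprint, tanimoto
from .properties import LOGP_METHOD, PropertySet, property_matrix

logger = logging.getLogger(__name__)

RF_SETTINGS = {"n_estimators": 50, "max_depth": None}


def _znorm_union(actives, decoys):
    X = np.vstack([actives, decoys])
    loc = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale <= 1e-12, 1.0, scale)
    return (np.asarray(actives, float) - loc) / scale, \
        (np.asarray(decoys, float) - loc) / scale


def _roc_curve_with_ties(pos_dist, neg_dist):
    """Breakpoints of the ROC over ascending distance, ties as one segment."""
    scores = np.concatenate([pos_dist, neg_dist])
    labels = np.concatenate([np.ones(len(pos_dist)),
                             np.zeros(len(neg_dist))])
    order = np.argsort(scores, kind="stable")
    scores, labels = scores[order], labels[order]
    xs, ys = [0.0], [0.0]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:
            j += 1
        tp += int(labels[i:j].sum())
        fp += (j - i) - int(labels[i:j].sum())
        xs.append(fp / max(len(neg_dist), 1))
        ys.append(tp / max(len(pos_dist), 1))
        i = j
    return np.array(xs), np.array(ys)


def _abs_area_from_diagonal(xs, ys):
    """Exact integral of |ROC(x) - x| over the piecewise-linear curve."""
    total = 0.0
    for (x0, y0), (x1, y1) in zip(zip(xs, ys), zip(xs[1:], ys[1:])):
        dx = x1 - x0
        if dx <= 0:
            continue
        f0, f1 = y0 - x0, y1 - x1
        if f0 * f1 >= 0:
            total += 0.5 * (abs(f0) + abs(f1)) * dx
        else:  # sign change inside the segment
            t = f0 / (f0 - f1)
            total += 0.5 * dx * (abs(f0) * t + abs(f1) * (1 - t))
    return total


def doe_score(actives, decoys, return_curves=False):
    """Deviation-from-optimal-embedding score in [0, 0.5].

    Parameters are property matrices, shape (n_actives, k) and
    (n_decoys, k); z-scoring on their union is applied internally.
    """
    actives = np.atleast_2d(np.asarray(actives, float))
    decoys = np.atleast_2d(np.asarray(decoys, float))
    if len(actives) < 2:
        raise ValueError("DOE needs at least 2 actives")
    if len(decoys) < 1:
        raise ValueError("DOE needs at least 1 decoy")
    za, zd = _znorm_union(actives, decoys)
    # round distances so mathematically tied values (which must share one
    # interpolated ROC segment) are not split by last-bit float noise
    d_aa = np.round(cdist(za, za), 9)
    d_ad = np.round(cdist(za, zd), 9)
    scores, curves = [], []
    for i in range(len(za)):
        pos = np.delete(d_aa[i], i)
        neg = d_ad[i]
        xs, ys = _roc_curve_with_ties(pos, neg)
        scores.append(_abs_area_from_diagonal(xs, ys))
        if return_curves:
            curves.append((xs, ys))
    doe = float(np.mean(scores))
    return (doe, curves) if return_curves else doe


class DoppelgangerResult(tuple):
    """(per_decoy, mean, max) doppelganger scores."""

    def __new__(cls, per_decoy):
        per_decoy = np.asarray(per_decoy, float)
        return super().__new__(cls, (per_decoy,
                                     float(per_decoy.mean()),
                                     float(per_decoy.max())))

    per_decoy = property(lambda s: s[0])
    mean = property(lambda s: s[1])
    max = property(lambda s: s[2])


def doppelganger_scores(decoys, actives) -> DoppelgangerResult:
    """Per-decoy maximum functional-fingerprint Tanimoto to any active."""
    if not len(decoys) or not len(actives):
        raise ValueError("need non-empty decoy and active sets")
    afps = [functional_fingerprint(a) for a in actives]
    per_decoy = [max(tanimoto(functional_fingerprint(d), a) for a in afps)
                 for d in decoys]
    return DoppelgangerResult(per_decoy)


def _hit_fraction(valid, train, thresholds):
    """Mean over valid points of the fraction of thresholds their
    nearest-train distance falls under (distances squashed to [0,1])."""
    if len(valid) == 0 or len(train) == 0:
        return None
    nn = NearestNeighbors(n_neighbors=1).fit(train)
    d = nn.kneighbors(valid)[0][:, 0]
    d = d / (1.0 + d)  # squash unbounded property distance into [0, 1)
    return float(np.mean([(d_i <= thresholds).mean() for d_i in d]))


def ave_bias(actives, decoys, n_folds=10, n_thresholds=50, seed=0) -> float:
    """Asymmetric validation embedding bias in [-2, 2].

    AVE = (H(VA,TA) - H(VA,TD)) + (H(VD,TD) - H(VD,TA)) averaged over
    stratified folds, where H is the threshold-averaged nearest-neighbour
    hit fraction from validation points V to training points T, A/D denote
    actives/decoys.  Positive values mean each class clumps with its own
    training data — i.e. the split is biased.
    """
    za, zd = _znorm_union(actives, decoys)
    X = np.vstack([za, zd])
    y = np.concatenate([np.ones(len(za)), np.zeros(len(zd))])
    thresholds = np.linspace(0.0, 1.0, n_thresholds)
    min_class = int(np.bincount(y.astype(int)).min())
    if min_class < 2:
        raise ValueError("AVE needs at least 2 members per class")
    n_folds = min(n_folds, min_class)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    vals = []
    for train_idx, val_idx in skf.split(X, y):
        ta = X[train_idx][y[train_idx] == 1]
        td = X[train_idx][y[train_idx] == 0]
        va = X[val_idx][y[val_idx] == 1]
        vd = X[val_idx][y[val_idx] == 0]
        terms = (_hit_fraction(va, ta, thresholds),
                 _hit_fraction(va, td, thresholds),
                 _hit_fraction(vd, td, thresholds),
                 _hit_fraction(vd, ta, thresholds))
        if any(t is None for t in terms):
            warnings.warn("fold skipped: empty class")
            continue
        vals.append((terms[0] - terms[1]) + (terms[2] - terms[3]))
    if not vals:
        raise ValueError("no usable folds for AVE")
    return float(np.mean(vals))


def _knn1_scores(Xtr, ytr, Xval):
    """Continuous 1NN score: distance to nearest decoy minus nearest
    active (higher = more active-like)."""
    na = NearestNeighbors(n_neighbors=1).fit(Xtr[ytr == 1])
    nd = NearestNeighbors(n_neighbors=1).fit(Xtr[ytr == 0])
    da = na.kneighbors(Xval)[0][:, 0]
    dd = nd.kneighbors(Xval)[0][:, 0]
    return dd - da


def ml_bias_assessment(actives, decoys, property_names, model_kind="1NN",
                       folds=10, seed=0):
    """Cross-validated AUC for every non-empty property subset.

    Returns ``{subset (tuple of names): auc}`` with ``2^k - 1`` entries.
    Scores are pooled out-of-fold before a single AUC per subset.  1NN uses
    a continuous nearest-neighbour distance margin; RF uses
    ``predict_proba`` with pinned settings (``RF_SETTINGS``).
    """
    if model_kind not in ("1NN", "RF"):
        raise ValueError("model_kind must be '1NN' or 'RF'")
    property_names = tuple(property_names)
    za, zd = _znorm_union(actives, decoys)
    X = np.vstack([za, zd])
    y = np.concatenate([np.ones(len(za)), np.zeros(len(zd))])
    min_class = int(np.bincount(y.astype(int)).min())
    if min_class < 2:
        raise ValueError("need at least 2 members per class")
    if min_class < folds:
        warnings.warn(f"reducing folds from {folds} to {min_class}")
        folds = min_class
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    table = {}
    k = len(property_names)
    for r in range(1, k + 1):
        for subset in itertools.combinations(range(k), r):
            Xs = X[:, subset]
            oof = np.empty(len(y))
            for tr, va in splits:
                if model_kind == "1NN":
                    oof[va] = _knn1_scores(Xs[tr], y[tr], Xs[va])
                else:
                    rf = RandomForestClassifier(random_state=seed,
                                                **RF_SETTINGS)
                    rf.fit(Xs[tr], y[tr])
                    oof[va] = rf.predict_proba(Xs[va])[:, 1]
            names = tuple(property_names[i] for i in subset)
            table[names] = float(roc_auc_score(y, oof))
    return table


def compile_report(target_name, actives, decoys, pset: PropertySet,
                   folds=10, seed=0, model_kinds=("1NN", "RF"),
                   subset_table=True) -> dict:
    """Full bias report for one target as a JSON-serialisable dict.

    Individual metric failures are recorded as null with a reason; the
    report is still emitted.  Byte-identical under a fixed seed.
    """
    Xa = property_matrix(actives, pset)
    Xd = property_matrix(decoys, pset)
    report = {
        "schema_version": 1,
        "target": target_name,
        "n_actives": len(actives),
        "n_decoys": len(decoys),
        "metadata": {
            "property_set": pset.name,
            "properties": list(pset.property_names),
            "normalization": "z-score on actives+decoys union",
            "fingerprint": FUNCTIONAL_FLAVOR,
            "logp_method": LOGP_METHOD,
            "rf_settings": RF_SETTINGS,
            "folds": folds,
            "seed": seed,
        },
        "errors": {},
    }
    try:
        report["doe_score"] = round(doe_score(Xa, Xd), 10)
    except Exception as exc:
        report["doe_score"] = None
        report["errors"]["doe_score"] = str(exc)
    try:
        dopp = doppelganger_scores(decoys, actives)
        report["doppelganger_mean"] = round(dopp.mean, 10)
        report["doppelganger_max"] = round(dopp.max, 10)
    except Exception as exc:
        report["doppelganger_mean"] = report["doppelganger_max"] = None
        report["errors"]["doppelganger"] = str(exc)
    try:
        report["ave"] = round(ave_bias(Xa, Xd, n_folds=folds, seed=seed), 10)
    except Exception as exc:
        report["ave"] = None
        report["errors"]["ave"] = str(exc)
    if subset_table:
        report["subset_auc"] = {}
        for kind in model_kinds:
            try:
                table = ml_bias_assessment(Xa, Xd, pset.property_names,
                                           model_kind=kind, folds=folds,
                                           seed=seed)
                report["subset_auc"][kind] = {
                    "+".join(names): round(auc, 10)
                    for names, auc in table.items()}
            except Exception as exc:
                report["subset_auc"][kind] = None
                report["errors"][f"subset_auc_{kind}"] = str(exc)
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
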