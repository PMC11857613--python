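"""Evaluation metrics, structure-disjoint splitting, and top-k tables.

Binary fingerprint predictions are scored with Tanimoto similarity
TP/(TP+FP+FN), F1 = 2PR/(P+R), and the Matthews correlation coefficient.
Annotation quality is reported as top-k accuracy: the fraction of query
spectra whose true compound (matched on the first 14 InChIKey characters)
ranks at or above k.  Structure-disjoint evaluation removes every training
spectrum whose compound shares an InChIKey first block with a test compound.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import models
from .models import ModelSpec, TrainConfig, binarize

__all__ = [
    "MetricCounts",
    "TopKTable",
    "confusion",
    "tanimoto",
    "f1",
    "mcc",
    "group_kfold",
    "crossval_metrics",
    "is_hit",
    "structure_disjoint_filter",
    "topk_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricCounts:
    """Confusion-matrix tallies for a binary comparison."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("counts must be non-negative")


def confusion(pred, truth) -> MetricCounts:
    """Count TP/FP/FN/TN between two equal-length binary vectors (or
    matrices, which are flattened)."""
    pred = np.asarray(pred).ravel().astype(bool)
    truth = np.asarray(truth).ravel().astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return MetricCounts(tp, fp, fn, tn)


def tanimoto(c: MetricCounts, denominator: str = "standard") -> float:
    """Tanimoto (Jaccard) similarity TP/(TP+FP+FN).

    ``denominator="printed"`` computes TP/(FP+FN-TP) instead — a variant
    that can leave [0,1] and is kept only for comparison; the standard form
    is the default and the one used everywhere in the package.  When
    TP+FP+FN = 0 (nothing positive anywhere) the similarity is 1 by
    convention.
    """
    if denominator == "printed":
        den = c.FP + c.FN - c.TP
        return math.inf if den == 0 else c.TP / den
    den = c.TP + c.FP + c.FN
    if den == 0:
        logger.debug("tanimoto on all-negative vectors; returning 1.0")
        return 1.0
    return c.TP / den


def f1(c: MetricCounts) -> float:
    """F1 = 2PR/(P+R).  All-negative truth and prediction (TP=FP=FN=0)
    scores 1.0; positives predicted but none exist, or existing but none
    predicted, scores 0.0."""
    if c.TP == 0:
        return 1.0 if c.FP == 0 and c.FN == 0 else 0.0
    precision = c.TP / (c.TP + c.FP)
    recall = c.TP / (c.TP + c.FN)
    return 2 * precision * recall / (precision + recall)


def mcc(c: MetricCounts) -> float:
    """Matthews correlation coefficient; 0 by convention when any marginal
    is empty."""
    den = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if den == 0:
        logger.debug("MCC denominator zero; returning 0.0")
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(den)


def group_kfold(groups, n_folds: int = 5, seed: int = 0):
    """Deterministic k-fold split on group identity.

    Groups are shuffled with the seed and dealt round-robin to folds, so
    all rows of one compound land in one fold.  Yields (train_idx, test_idx)
    pairs.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < n_folds:
        raise ValueError(f"{len(uniq)} groups cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    uniq = rng.permutation(uniq)
    assignment = {g: i % n_folds for i, g in enumerate(uniq)}
    fold_of_row = np.array([assignment[g] for g in groups])
    for k in range(n_folds):
        yield np.flatnonzero(fold_of_row != k), np.flatnonzero(fold_of_row == k)


def crossval_metrics(
    spec: ModelSpec,
    X,
    Y,
    groups=None,
    n_folds: int = 5,
    seed: int = 0,
    config: TrainConfig | None = None,
    threshold: float = 0.5,
) -> dict:
    """Compound-level k-fold cross-validation of a fingerprint model.

    F1 and Tanimoto are micro-averaged over all bits of the concatenated
    held-out predictions; MCC is computed per bit and then averaged.
    Returns per-fold values and their means.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    groups = np.arange(X.shape[0]) if groups is None else np.asarray(groups)
    per_fold = {"f1": [], "tanimoto": [], "mcc": []}
    all_pred, all_truth = [], []
    for fold_i, (tr, te) in enumerate(group_kfold(groups, n_folds, seed)):
        fold_spec = ModelSpec(
            spec.architecture, spec.input_length, spec.output_length,
            layer_plan=spec.layer_plan, seed=spec.seed + fold_i,
        )
        res = models.train(fold_spec, X[tr], Y[tr], config, groups=groups[tr])
        pred = binarize(res.predict(X[te]), threshold)
        c = confusion(pred, Y[te])
        per_fold["f1"].append(f1(c))
        per_fold["tanimoto"].append(tanimoto(c))
        per_fold["mcc"].append(_mean_mcc(pred, Y[te]))
        all_pred.append(pred)
        all_truth.append(Y[te])
    pred = np.vstack(all_pred)
    truth = np.vstack(all_truth)
    c = confusion(pred, truth)
    # headline metrics use the concatenated held-out predictions: per-fold
    # MCC is systematically deflated by bits that happen to be constant
    # within one small fold (convention 0), which concatenation avoids
    return {
        "per_fold": per_fold,
        "fold_mean": {k: float(np.mean(v)) for k, v in per_fold.items()},
        "mean": {"f1": f1(c), "tanimoto": tanimoto(c),
                 "mcc": _mean_mcc(pred, truth)},
    }


def _mean_mcc(pred: np.ndarray, truth: np.ndarray) -> float:
    """Per-bit MCC averaged over fingerprint bits ("mean MCC")."""
    vals = [mcc(confusion(pred[:, j], truth[:, j])) for j in range(pred.shape[1])]
    return float(np.mean(vals))


def is_hit(candidate_inchikey: str, truth_inchikey: str) -> bool:
    """A candidate is a hit when it shares the InChIKey first block (the
    14-character skeleton hash) with the truth."""
    for key in (candidate_inchikey, truth_inchikey):
        if not isinstance(key, str) or len(key) != 27 or key[14] != "-":
            raise ValueError(f"malformed InChIKey: {key!r}")
    return candidate_inchikey[:14] == truth_inchikey[:14]


def structure_disjoint_filter(train_spectra, test_compounds):
    """Drop training spectra whose compound skeleton appears in the test set.

    ``test_compounds`` may be InChIKey strings or objects with an
    ``inchikey`` attribute (on ``.metadata`` for spectra).  Training records
    without an InChIKey are dropped and counted.
    """

    def _key(obj):
        if isinstance(obj, str):
            return obj
        if hasattr(obj, "inchikey"):
            return obj.inchikey
        return obj.metadata.inchikey

    test_blocks = {_key(c)[:14] for c in test_compounds}
    retained, dropped_missing = [], 0
    for s in train_spectra:
        key = _key(s)
        if key is None:
            dropped_missing += 1
            continue
        if key[:14] not in test_blocks:
            retained.append(s)
    if dropped_missing:
        logger.warning("dropped %d training records lacking an InChIKey",
                       dropped_missing)
    if not retained:
        logger.warning("structure-disjoint filter removed every training record")
    return retained


@dataclass
class TopKTable:
    """Top-k accuracy over a challenge set (fractions non-decreasing in k)."""

    ks: list[int]
    fractions: list[float]
    n_challenges: int
    mode_breakdown: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {f"top{k}": f for k, f in zip(self.ks, self.fractions)}


def topk_table(hit_ranks, ks=(1, 3, 5, 10), modes=None) -> TopKTable:
    """Build a top-k table from per-challenge ranks of the true compound.

    ``hit_ranks`` holds one entry per challenge: the rank (>= 1) or None
    for a miss.  ``modes`` optionally labels each challenge for a per-mode
    breakdown.
    """
    hit_ranks = list(hit_ranks)
    if not hit_ranks:
        raise ValueError("no challenges")
    ks = list(ks)

    def _fracs(ranks):
        return [
            sum(1 for r in ranks if r is not None and r <= k) / len(ranks)
            for k in ks
        ]

    breakdown = {}
    if modes is not None:
        modes = list(modes)
        for m in sorted(set(modes)):
            sub = [r for r, mm in zip(hit_ranks, modes) if mm == m]
            breakdown[m] = _fracs(sub)
    return TopKTable(ks, _fracs(hit_ranks), len(hit_ranks), breakdown)
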