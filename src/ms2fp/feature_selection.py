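"""Supervised selection of m/z bins and of predictable fingerprint bits.

Bin selection trains one tiny single-input probe network per candidate bin
against all fingerprint bits and scores the bin by its cross-validated
micro-averaged F1; the top 500 bins are kept.  Fingerprint selection then
trains a small convolutional probe on the selected bins and keeps the bits
whose per-bit cross-validated F1 exceeds 0.8.  Folds are always split on
compound identity so replicate spectra of one compound never straddle a
fold.  Both steps are run separately for positive- and negative-mode data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from . import nn
from .evaluate import confusion, f1 as f1_score, group_kfold
from .models import binarize

__all__ = [
    "FeatureScore",
    "SelectionConfig",
    "score_bins",
    "select_top_bins",
    "score_fingerprint_bits",
    "select_fingerprints",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureScore:
    """Cross-validated F1 of one feature (a bin or a fingerprint bit)."""

    feature_index: int
    f1: float
    fold_scores: list[float] = field(default_factory=list)

    def __post_init__(self):
        if self.fold_scores and not np.isclose(self.f1, np.mean(self.fold_scores)):
            raise ValueError("f1 must equal the mean of fold_scores")


@dataclass
class SelectionConfig:
    """Feature-selection parameters (defaults = study conditions)."""

    n_bins_keep: int = 500
    fp_f1_threshold: float = 0.8
    n_folds: int = 5
    seed: int = 0
    # probe hyperparameters
    bin_probe_hidden: int = 32
    fp_probe_filters: int = 32
    fp_probe_width: int = 5
    fp_probe_dense: int = 64
    probe_epochs: int = 20
    probe_batch: int = 128
    probe_lr: float = 0.01
    threshold: float = 0.5

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.fp_f1_threshold < 1:
            raise ValueError("fp_f1_threshold must be in (0, 1)")


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if sparse.issparse(X) else X, dtype=float)


def _bin_probe(n_out: int, cfg: SelectionConfig, seed: int) -> nn.Network:
    return nn.Network(
        [
            nn.Dense(1, cfg.bin_probe_hidden),
            nn.ReLU(),
            nn.Dense(cfg.bin_probe_hidden, n_out),
            nn.Sigmoid(),
        ],
        loss=nn.BCELoss(),
        seed=seed,
    )


def _fp_probe(n_in: int, n_out: int, cfg: SelectionConfig, seed: int) -> nn.Network:
    conv_out = (n_in - cfg.fp_probe_width + 1) // 2
    return nn.Network(
        [
            nn.Reshape1C(),
            nn.Conv1D(1, cfg.fp_probe_filters, cfg.fp_probe_width),
            nn.ReLU(),
            nn.MaxPool1D(2),
            nn.Flatten(),
            nn.Dense(conv_out * cfg.fp_probe_filters, cfg.fp_probe_dense),
            nn.ReLU(),
            nn.Dense(cfg.fp_probe_dense, n_out),
            nn.Sigmoid(),
        ],
        loss=nn.BCELoss(),
        seed=seed,
    )


def score_bins(X, Y, cfg: SelectionConfig | None = None, groups=None) -> list[FeatureScore]:
    """Score every bin by the cross-validated micro-F1 of a per-bin probe.

    For each bin a one-input network is trained against all fingerprint
    bits on each training fold and evaluated (micro-averaged F1 over every
    bit of the held-out rows); the bin's score is the mean over folds.
    Bins that are zero in every spectrum score 0 without training.
    """
    cfg = cfg or SelectionConfig()
    X = _dense(X)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be row-aligned")
    groups = np.arange(X.shape[0]) if groups is None else np.asarray(groups)
    folds = list(group_kfold(groups, cfg.n_folds, cfg.seed))
    scores: list[FeatureScore] = []
    for j in range(X.shape[1]):
        col = X[:, j : j + 1]
        if not col.any():
            scores.append(FeatureScore(j, 0.0, [0.0] * cfg.n_folds))
            continue
        fold_scores = []
        for fold_i, (tr, te) in enumerate(folds):
            # seed depends on the fold only, so identical columns get
            # identical probes and hence identical scores
            net = _bin_probe(Y.shape[1], cfg, seed=cfg.seed + fold_i)
            net.fit(
                col[tr], Y[tr],
                epochs=cfg.probe_epochs, batch_size=cfg.probe_batch,
                lr=cfg.probe_lr, patience=None,
            )
            pred = binarize(net.forward(col[te]), cfg.threshold)
            fold_scores.append(f1_score(confusion(pred, Y[te])))
        scores.append(FeatureScore(j, float(np.mean(fold_scores)), fold_scores))
    return scores


def select_top_bins(scores: list[FeatureScore], k: int = 500) -> np.ndarray:
    """Indices of the min(k, n) highest-F1 bins, ties broken toward the
    lower index; returned sorted ascending for a stable column order."""
    order = sorted(scores, key=lambda s: (-s.f1, s.feature_index))
    top = [s.feature_index for s in order[: min(k, len(scores))]]
    return np.array(sorted(top), dtype=int)


def score_fingerprint_bits(
    X_sel, Y, cfg: SelectionConfig | None = None, groups=None
) -> list[FeatureScore]:
    """Per-fingerprint-bit cross-validated F1 of one convolutional probe.

    One multi-output probe is trained per fold on the selected bins; F1 is
    computed for every output bit on the held-out rows.  A bit with no
    positive examples in a fold scores 0 for that fold (logged).
    """
    cfg = cfg or SelectionConfig()
    X_sel = _dense(X_sel)
    Y = np.asarray(Y, dtype=float)
    groups = np.arange(X_sel.shape[0]) if groups is None else np.asarray(groups)
    n_bits = Y.shape[1]
    per_bit_folds: list[list[float]] = [[] for _ in range(n_bits)]
    for fold_i, (tr, te) in enumerate(group_kfold(groups, cfg.n_folds, cfg.seed)):
        net = _fp_probe(X_sel.shape[1], n_bits, cfg, seed=cfg.seed + fold_i)
        net.fit(
            X_sel[tr], Y[tr],
            epochs=cfg.probe_epochs, batch_size=cfg.probe_batch,
            lr=cfg.probe_lr, patience=None,
        )
        pred = binarize(net.forward(X_sel[te]), cfg.threshold)
        for b in range(n_bits):
            if not Y[te, b].any():
                logger.debug("bit %d has no positives in fold %d", b, fold_i)
                per_bit_folds[b].append(0.0)
            else:
                per_bit_folds[b].append(f1_score(confusion(pred[:, b], Y[te, b])))
    return [
        FeatureScore(b, float(np.mean(fs)), fs) for b, fs in enumerate(per_bit_folds)
    ]


def select_fingerprints(scores: list[FeatureScore], threshold: float = 0.8) -> np.ndarray:
    """Indices with F1 strictly above the threshold (0.8 exactly is out)."""
    kept = np.array(
        [s.feature_index for s in scores if s.f1 > threshold], dtype=int
    )
    if kept.size == 0:
        logger.warning("no fingerprint bit exceeded F1 %.2f", threshold)
    return kept
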