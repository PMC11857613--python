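"""Candidate retrieval by precursor m/z, fingerprint scoring, score fusion,
and ranking.

For a query spectrum the neutral monoisotopic mass is computed under each
mode-consistent adduct hypothesis ([M+H]+, [M+NH4]+, [M+Na]+ in positive
mode; [M-H]-, [M+Cl]-, [M+FA-H]- in negative mode) and compounds whose mass
falls within a 5 ppm window are retrieved.  Each candidate is scored by the
Tanimoto similarity between the model-predicted fingerprint and its own, the
external formula-prediction score (when present) is min-max normalized
within the challenge, and the two are fused 7:3 into an overall score that
drives the final ranking.  Ties get the pessimistic (worst-of-block) rank so
top-k is never inflated.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import binarize

__all__ = [
    "ADDUCTS",
    "CompoundRecord",
    "ScoredCandidate",
    "RetrievalConfig",
    "adducts_for_mode",
    "neutral_mass",
    "load_compound_table",
    "retrieve_candidates",
    "fingerprint_score",
    "minmax_normalize",
    "combine_scores",
    "rank_candidates",
    "random_baseline",
]

logger = logging.getLogger(__name__)

# Monoisotopic shift from the neutral mass M to the measured precursor m/z,
# electron mass folded in (singly charged ions).
ADDUCTS: dict[str, tuple[str, float]] = {
    "[M+H]+": ("positive", 1.007276),
    "[M+NH4]+": ("positive", 18.033823),
    "[M+Na]+": ("positive", 22.989218),
    "[M-H]-": ("negative", -1.007276),
    "[M+Cl]-": ("negative", 34.969401),
    "[M+FA-H]-": ("negative", 44.998201),
}


def adducts_for_mode(mode: str) -> list[str]:
    return [a for a, (m, _) in ADDUCTS.items() if m == mode]


def neutral_mass(precursor_mz: float, adduct: str) -> float:
    """Neutral monoisotopic mass implied by a precursor m/z and adduct."""
    if adduct not in ADDUCTS:
        raise ValueError(f"unknown adduct {adduct!r}")
    return precursor_mz - ADDUCTS[adduct][1]


@dataclass
class CompoundRecord:
    """One database entry: identifiers, mass, and (optionally) the
    precomputed full-length fingerprint."""

    compound_id: str
    smiles: str
    inchikey: str
    formula: str
    monoisotopic_mass: float
    fingerprint: np.ndarray | None = None

    def __post_init__(self):
        if not self.monoisotopic_mass > 0:
            raise ValueError("monoisotopic_mass must be positive")


@dataclass
class ScoredCandidate:
    """A retrieved candidate with its scores and final rank."""

    record: CompoundRecord
    adducts: list[str]
    fingerprint_score: float = float("nan")
    formula_score_raw: float | None = None
    formula_score_norm: float | None = None
    overall_score: float = float("nan")
    rank: int = 0

    @property
    def adduct(self) -> str:
        return "|".join(self.adducts)


@dataclass
class RetrievalConfig:
    ppm_tolerance: float = 5.0
    fp_weight: float = 0.7
    formula_weight: float = 0.3
    score_space: str = "binary"  # or "probability"

    def __post_init__(self):
        if self.ppm_tolerance <= 0:
            raise ValueError("ppm_tolerance must be positive")
        if not np.isclose(self.fp_weight + self.formula_weight, 1.0):
            raise ValueError("fp_weight + formula_weight must equal 1")
        if self.score_space not in ("binary", "probability"):
            raise ValueError("score_space must be 'binary' or 'probability'")


def load_compound_table(path, fingerprint_column: str = "fingerprint") -> list[CompoundRecord]:
    """Read a compound database TSV (id, smiles, inchikey, formula,
    monoisotopic_mass[, fingerprint as a 0/1 string])."""
    df = pd.read_csv(path, sep="\t", dtype={fingerprint_column: str})
    records = []
    for row in df.itertuples(index=False):
        fp = None
        if fingerprint_column in df.columns:
            s = getattr(row, fingerprint_column)
            if isinstance(s, str) and s:
                fp = np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")
        records.append(
            CompoundRecord(
                compound_id=str(row.id),
                smiles="" if pd.isna(row.smiles) else str(row.smiles),
                inchikey=str(row.inchikey),
                formula=str(row.formula),
                monoisotopic_mass=float(row.monoisotopic_mass),
                fingerprint=fp,
            )
        )
    return records


def retrieve_candidates(
    precursor_mz: float,
    mode: str,
    db: list[CompoundRecord],
    cfg: RetrievalConfig | None = None,
) -> list[ScoredCandidate]:
    """Retrieve all compounds within the ppm window under any mode-consistent
    adduct.  A compound matching under several adducts appears once, tagged
    with all of them.  The window is relative to the hypothesis neutral
    mass: |mass - M| / M <= ppm * 1e-6.
    """
    cfg = cfg or RetrievalConfig()
    if not db:
        raise ValueError("empty compound database")
    order = sorted(range(len(db)), key=lambda i: db[i].monoisotopic_mass)
    masses = [db[i].monoisotopic_mass for i in order]
    hits: dict[int, list[str]] = {}
    for adduct in adducts_for_mode(mode):
        m = neutral_mass(precursor_mz, adduct)
        half = cfg.ppm_tolerance * 1e-6 * m
        lo = bisect.bisect_left(masses, m - half)
        hi = bisect.bisect_right(masses, m + half)
        for k in range(lo, hi):
            hits.setdefault(order[k], []).append(adduct)
    return [ScoredCandidate(db[i], hits[i]) for i in sorted(hits)]


def fingerprint_score(predicted: np.ndarray, candidate_bits: np.ndarray,
                      space: str = "binary") -> float:
    """Tanimoto similarity between the predicted fingerprint and a
    candidate's bits, in the model's condensed/selected space.

    ``binary`` thresholds the prediction at 0.5 first; ``probability`` uses
    the soft form sum(p*y) / (sum(p) + sum(y) - sum(p*y)).
    """
    predicted = np.asarray(predicted, dtype=float)
    y = np.asarray(candidate_bits, dtype=float)
    if predicted.shape != y.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {y.shape}")
    if space == "binary":
        p = binarize(predicted).astype(float)
    elif space == "probability":
        p = predicted
    else:
        raise ValueError("space must be 'binary' or 'probability'")
    inter = float((p * y).sum())
    union = float(p.sum() + y.sum() - inter)
    return 1.0 if union == 0 else inter / union


def minmax_normalize(scores) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant (or singleton) input maps to
    all ones so the fused score stays attainable at its upper bound."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("cannot normalize an empty score list")
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        return np.ones_like(scores)
    return (scores - lo) / (hi - lo)


def combine_scores(fp: float, formula_norm: float | None,
                   cfg: RetrievalConfig | None = None) -> float:
    """Fuse fingerprint and normalized formula scores 7:3; candidates
    without a formula score keep the fingerprint score alone."""
    cfg = cfg or RetrievalConfig()
    if formula_norm is None:
        return fp
    return cfg.fp_weight * fp + cfg.formula_weight * formula_norm


def rank_candidates(candidates: list[ScoredCandidate]) -> list[ScoredCandidate]:
    """Order by descending overall score (secondary: compound id) and assign
    pessimistic ranks: every member of a tied block gets the block's worst
    rank."""
    ordered = sorted(
        candidates, key=lambda c: (-c.overall_score, c.record.compound_id)
    )
    n = len(ordered)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ordered[j + 1].overall_score == ordered[i].overall_score:
            j += 1
        for k in range(i, j + 1):
            ordered[k].rank = j + 1
        i = j + 1
    return ordered


def score_and_rank(
    candidates: list[ScoredCandidate],
    predicted_fp: np.ndarray,
    candidate_fps: list[np.ndarray],
    formula_scores: dict[str, float] | None = None,
    cfg: RetrievalConfig | None = None,
) -> list[ScoredCandidate]:
    """Score retrieved candidates against a predicted fingerprint and rank.

    ``candidate_fps`` holds each candidate's fingerprint already projected
    into the model's output space; ``formula_scores`` maps formula text to
    the external tool's raw score for this challenge.
    """
    cfg = cfg or RetrievalConfig()
    for cand, bits in zip(candidates, candidate_fps):
        cand.fingerprint_score = fingerprint_score(predicted_fp, bits, cfg.score_space)
    if formula_scores:
        scored = [c for c in candidates if c.record.formula in formula_scores]
        if scored:
            raw = [formula_scores[c.record.formula] for c in scored]
            norm = minmax_normalize(raw)
            for c, r, nv in zip(scored, raw, norm):
                c.formula_score_raw = float(r)
                c.formula_score_norm = float(nv)
    for c in candidates:
        c.overall_score = combine_scores(c.fingerprint_score, c.formula_score_norm, cfg)
    return rank_candidates(candidates)


def random_baseline(
    candidate_lists: list[tuple[list[str], str]],
    n_shuffles: int = 100,
    ks=(1, 3, 5, 10),
    seed: int = 0,
) -> dict[int, float]:
    """Average top-k fractions when each challenge's candidates are listed in
    random order ``n_shuffles`` times.

    ``candidate_lists`` holds (candidate_ids, true_id) per challenge.  A
    challenge whose list lacks its true compound counts as a miss.  The
    expectation per challenge is min(k, N)/N.
    """
    rng = np.random.default_rng(seed)
    ks = list(ks)
    totals = {k: 0.0 for k in ks}
    n_chal = len(candidate_lists)
    if n_chal == 0:
        raise ValueError("no challenges")
    for ids, true_id in candidate_lists:
        ids = list(ids)
        if true_id not in ids:
            logger.warning("true compound %s missing from its candidate list", true_id)
            continue
        for _ in range(n_shuffles):
            perm = rng.permutation(len(ids))
            pos = int(np.flatnonzero(perm == ids.index(true_id))[0])
            # pos is the shuffled position (0-based) of the true compound
            for k in ks:
                if pos < k:
                    totals[k] += 1.0
    return {k: totals[k] / (n_shuffles * n_chal) for k in ks}
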