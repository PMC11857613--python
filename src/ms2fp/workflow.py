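"""End-to-end glue: train an annotation pipeline from annotated spectra and
apply it to query spectra.

``fit_pipeline`` chains the stages in their fixed order — preprocessing and
binning, bin-occupancy filtering, fingerprint condensation, supervised bin
and fingerprint selection, model training — and returns an
:class:`AnnotationPipeline` that can embed query spectra, predict their
fingerprints, retrieve candidates by precursor m/z, fuse scores and rank.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from .evaluate import is_hit
from .feature_selection import (
    SelectionConfig,
    score_bins,
    score_fingerprint_bits,
    select_fingerprints,
    select_top_bins,
)
from .fingerprints import CondensedMap, build_condensed_map, project
from .models import FingerprintModelResults, ModelSpec, TrainConfig, train
from .preprocessing import (
    BinGrid,
    PreprocessConfig,
    bin_spectrum,
    preprocess_spectra,
    restrict_peaks,
    scale_intensities,
    select_top_peaks,
)
from .spectra_io import Spectrum

__all__ = ["AnnotationPipeline", "fit_pipeline", "annotate_queries"]

logger = logging.getLogger(__name__)


@dataclass
class AnnotationPipeline:
    """A trained model plus everything needed to apply it to new spectra:
    the bin grid, the selected grid bins, the selected condensed fingerprint
    columns, and the condensation map."""

    results: FingerprintModelResults
    pre_cfg: PreprocessConfig
    selected_bins: np.ndarray  # indices into the full grid
    selected_fps: np.ndarray  # indices into the condensed space
    cmap: CondensedMap
    mode: str = "positive"

    def embed(self, s: Spectrum) -> np.ndarray:
        """Scale, restrict, cap and bin one query spectrum, then take the
        model's selected bins (the spectrum-quality filters are a training
        concern and are not applied to queries)."""
        s = scale_intensities(s, self.pre_cfg.intensity_max)
        s = restrict_peaks(s, self.pre_cfg)
        s = select_top_peaks(s, self.pre_cfg.top_n_peaks)
        vec = bin_spectrum(s, self.pre_cfg.grid).toarray()
        return vec[self.selected_bins]

    def predict_fingerprint(self, s: Spectrum) -> np.ndarray:
        return self.results.predict(self.embed(s))

    def project_candidate(self, full_fp: np.ndarray) -> np.ndarray:
        return project(full_fp, self.cmap).bits[self.selected_fps]

    def save(self, directory) -> None:
        d = Path(directory)
        self.results.save(d)
        meta = {
            "mode": self.mode,
            "grid": {
                "mass_low": self.pre_cfg.grid.mass_low,
                "mass_high": self.pre_cfg.grid.mass_high,
                "width": self.pre_cfg.grid.width,
            },
            "preprocess": {
                "intensity_max": self.pre_cfg.intensity_max,
                "min_peaks": self.pre_cfg.min_peaks,
                "top_n_peaks": self.pre_cfg.top_n_peaks,
                "min_scaled_intensity": self.pre_cfg.min_scaled_intensity,
                "occupancy_fraction": self.pre_cfg.occupancy_fraction,
            },
            "selected_bins": [int(i) for i in self.selected_bins],
            "selected_fps": [int(i) for i in self.selected_fps],
        }
        (d / "pipeline.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory) -> "AnnotationPipeline":
        d = Path(directory)
        meta = json.loads((d / "pipeline.json").read_text())
        results = FingerprintModelResults.load(d)
        pre = PreprocessConfig(grid=BinGrid(**meta["grid"]), **meta["preprocess"])
        return cls(
            results=results,
            pre_cfg=pre,
            selected_bins=np.array(meta["selected_bins"], dtype=int),
            selected_fps=np.array(meta["selected_fps"], dtype=int),
            cmap=results.condensed_map,
            mode=meta["mode"],
        )


def fit_pipeline(
    spectra: list[Spectrum],
    compound_fingerprints: dict[str, np.ndarray],
    architecture: str = "conv",
    families: tuple | None = None,
    pre_cfg: PreprocessConfig | None = None,
    sel_cfg: SelectionConfig | None = None,
    train_cfg: TrainConfig | None = None,
    mode: str = "positive",
    seed: int = 0,
) -> AnnotationPipeline:
    """Train the full pipeline on one ionization mode's spectra.

    ``compound_fingerprints`` maps each spectrum's compound_id to its
    full-length binary fingerprint.  Feature selection and the model's
    validation split both group rows by compound.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    sel_cfg = sel_cfg or SelectionConfig(seed=seed)
    spectra = [s for s in spectra if s.metadata.ionization_mode == mode]
    X, retained_bins, kept = preprocess_spectra(spectra, pre_cfg)
    groups = np.array([s.metadata.compound_id for s in kept])

    # condensation map from the distinct training compounds
    train_ids = list(dict.fromkeys(groups.tolist()))
    fp_matrix = np.vstack([compound_fingerprints[cid] for cid in train_ids])
    n_bits = fp_matrix.shape[1]
    cmap = build_condensed_map(
        fp_matrix, families=families or (("planted", n_bits),)
    )
    condensed_by_id = {
        cid: project(compound_fingerprints[cid], cmap).bits for cid in train_ids
    }
    Y = np.vstack([condensed_by_id[g] for g in groups])

    bin_scores = score_bins(X, Y, sel_cfg, groups)
    sel_cols = select_top_bins(bin_scores, sel_cfg.n_bins_keep)
    X_sel = np.asarray(X[:, sel_cols].todense(), dtype=float)
    fp_scores = score_fingerprint_bits(X_sel, Y, sel_cfg, groups)
    sel_fps = select_fingerprints(fp_scores, sel_cfg.fp_f1_threshold)
    if sel_fps.size == 0:
        logger.warning("no fingerprint bit passed selection; keeping all bits")
        sel_fps = np.arange(Y.shape[1])

    spec = ModelSpec(architecture, len(sel_cols), len(sel_fps), seed=seed)
    results = train(
        spec, X_sel, Y[:, sel_fps], train_cfg, groups=groups,
        selected_bins=retained_bins[sel_cols], selected_fps=sel_fps,
        condensed_map=cmap, mode=mode,
    )
    return AnnotationPipeline(
        results=results,
        pre_cfg=pre_cfg,
        selected_bins=retained_bins[sel_cols],
        selected_fps=sel_fps,
        cmap=cmap,
        mode=mode,
    )


def annotate_queries(
    pipeline: AnnotationPipeline,
    queries: list[Spectrum],
    db: list[ann.CompoundRecord],
    formula_scores: pd.DataFrame | None = None,
    cfg: ann.RetrievalConfig | None = None,
    truth: pd.DataFrame | None = None,
):
    """Annotate query spectra against a compound database.

    Returns ``(ranked, hit_ranks)``: a long-format frame with one row per
    (challenge, candidate) holding rank and scores, and — when ``truth``
    maps challenge_id to the true InChIKey — the per-challenge rank of the
    first hit (None for a miss, using the InChIKey first-block rule).
    """
    cfg = cfg or ann.RetrievalConfig()
    scores_by_challenge: dict[str, dict[str, float]] = {}
    if formula_scores is not None and len(formula_scores):
        for cid, sub in formula_scores.groupby("challenge_id"):
            scores_by_challenge[str(cid)] = dict(
                zip(sub["formula"].astype(str), sub["score"].astype(float))
            )
    truth_keys = (
        dict(zip(truth["challenge_id"].astype(str), truth["inchikey"].astype(str)))
        if truth is not None
        else {}
    )
    rows = []
    hit_ranks: list[int | None] = []
    for qi, q in enumerate(queries):
        challenge_id = q.metadata.compound_id or f"challenge{qi}"
        if q.metadata.precursor_mz is None:
            logger.warning("query %s has no precursor m/z; skipped", challenge_id)
            hit_ranks.append(None)
            continue
        candidates = ann.retrieve_candidates(
            q.metadata.precursor_mz, q.metadata.ionization_mode, db, cfg
        )
        if not candidates:
            hit_ranks.append(None)
            continue
        predicted = pipeline.predict_fingerprint(q)
        cand_fps = [pipeline.project_candidate(c.record.fingerprint) for c in candidates]
        ranked = ann.score_and_rank(
            candidates, predicted, cand_fps,
            scores_by_challenge.get(challenge_id), cfg,
        )
        rank_of_hit = None
        for c in ranked:
            rows.append(
                {
                    "challenge_id": challenge_id,
                    "rank": c.rank,
                    "compound_id": c.record.compound_id,
                    "inchikey": c.record.inchikey,
                    "adduct": c.adduct,
                    "fp_score": c.fingerprint_score,
                    "formula_score_norm": c.formula_score_norm,
                    "overall_score": c.overall_score,
                }
            )
            if challenge_id in truth_keys and is_hit(
                c.record.inchikey, truth_keys[challenge_id]
            ):
                if rank_of_hit is None or c.rank < rank_of_hit:
                    rank_of_hit = c.rank
        hit_ranks.append(rank_of_hit)
    ranked_df = pd.DataFrame(
        rows,
        columns=[
            "challenge_id", "rank", "compound_id", "inchikey", "adduct",
            "fp_score", "formula_score_norm", "overall_score",
        ],
    )
    return ranked_df, hit_ranks
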