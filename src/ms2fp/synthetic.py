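"""Synthetic fixtures: compounds, spectra with a planted fingerprint->peak
rule, decoy databases, and external formula-score files.

The generator plants a learnable ground truth: a global codebook drawn once
per seed assigns every fingerprint bit a set of characteristic fragment m/z
values inside 100-1010 Da, and a compound's spectrum contains exactly the
peaks of its active bits (plus optional Poisson noise peaks and log-normal
intensity jitter).  Compounds carry InChIKey-like identifiers and uniform
masses in 150-900 Da; decoys sit at controlled ppm offsets from their true
compound with a fixed fingerprint Hamming distance and a different InChIKey
skeleton, so retrieval, ranking, and the hit rule are all exercised
honestly.  Everything is deterministic under the seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import CompoundRecord
from .spectra_io import NEGATIVE, POSITIVE, Peak, Spectrum, SpectrumMetadata, write_msp

__all__ = [
    "SynthConfig",
    "SyntheticCompound",
    "generate_compounds",
    "fragment_codebook",
    "generate_spectra",
    "generate_database",
    "generate_formula_scores",
    "generate_dataset",
]

PROTON = 1.007276


@dataclass
class SynthConfig:
    """Generator parameters.  The defaults define the standard desk-scale
    conditions used throughout the test suite: 50 compounds with 64-bit
    fingerprints, four replicate spectra each, noiseless peaks, and five
    decoys per compound at 4 bit flips within 0.5-10 ppm."""

    n_compounds: int = 50
    n_bits: int = 64
    bits_per_compound: float = 10.0
    n_spectra_per_compound: int = 4
    peaks_per_bit: int = 1
    noise_peak_rate: float = 0.0
    intensity_noise_sd: float = 0.0
    decoys_per_compound: int = 5
    decoy_bit_flips: int = 4
    decoy_ppm_offset_range: tuple[float, float] = (0.5, 10.0)
    missing_formula_fraction: float = 0.0
    mode: str = POSITIVE
    seed: int = 0

    def __post_init__(self):
        if min(self.n_compounds, self.n_bits, self.n_spectra_per_compound,
               self.peaks_per_bit, self.decoys_per_compound) <= 0:
            raise ValueError("counts must be positive")
        if self.decoy_bit_flips < 1:
            raise ValueError("decoys must differ from the truth by >= 1 bit")
        if self.mode not in (POSITIVE, NEGATIVE):
            raise ValueError("mode must be positive or negative")


@dataclass
class SyntheticCompound:
    compound_id: str
    inchikey: str
    formula: str
    mass: float
    fingerprint: np.ndarray


def _inchikey_like(rng: np.random.Generator) -> str:
    letters = np.array(list(string.ascii_uppercase))
    block1 = "".join(rng.choice(letters, 14))
    block2 = "".join(rng.choice(letters, 10))
    return f"{block1}-{block2}-N"


def _formula_like(rng: np.random.Generator) -> str:
    return (
        f"C{rng.integers(5, 40)}H{rng.integers(6, 60)}"
        f"N{rng.integers(0, 6)}O{rng.integers(0, 10)}"
    )


def generate_compounds(cfg: SynthConfig) -> list[SyntheticCompound]:
    """Draw compounds with i.i.d. Bernoulli fingerprints (mean activity =
    bits_per_compound/n_bits, at least one active bit), unique InChIKey-like
    identifiers, and masses uniform in [150, 900] Da."""
    rng = np.random.default_rng(cfg.seed)
    p_active = cfg.bits_per_compound / cfg.n_bits
    seen_keys: set[str] = set()
    seen_formulas: set[str] = set()
    compounds = []
    for i in range(cfg.n_compounds):
        fp = (rng.random(cfg.n_bits) < p_active).astype(np.uint8)
        if not fp.any():
            fp[rng.integers(cfg.n_bits)] = 1
        key = _inchikey_like(rng)
        while key[:14] in seen_keys:
            key = _inchikey_like(rng)
        seen_keys.add(key[:14])
        formula = _formula_like(rng)
        while formula in seen_formulas:
            formula = _formula_like(rng)
        seen_formulas.add(formula)
        compounds.append(
            SyntheticCompound(
                compound_id=f"SYN{i:05d}",
                inchikey=key,
                formula=formula,
                mass=float(rng.uniform(150.0, 900.0)),
                fingerprint=fp,
            )
        )
    return compounds


def fragment_codebook(cfg: SynthConfig) -> np.ndarray:
    """The planted bit->fragment rule: an (n_bits, peaks_per_bit) array of
    characteristic m/z values, global per seed, all inside 100-1010 Da and
    mapping to distinct 0.01 Da bins."""
    rng = np.random.default_rng(cfg.seed + 1000)
    used_bins: set[int] = set()
    mzs = np.empty((cfg.n_bits, cfg.peaks_per_bit))
    for b in range(cfg.n_bits):
        for r in range(cfg.peaks_per_bit):
            while True:
                mz = float(rng.uniform(100.5, 1009.5))
                bin_i = int((mz - 100.0) / 0.01)
                if bin_i not in used_bins:
                    used_bins.add(bin_i)
                    mzs[b, r] = mz
                    break
    return mzs


def generate_spectra(
    compounds: list[SyntheticCompound], cfg: SynthConfig
) -> list[Spectrum]:
    """Emit ``n_spectra_per_compound`` spectra per compound.

    Each active fingerprint bit contributes its codebook peaks with
    intensity 100*exp(N(0, intensity_noise_sd)); Poisson(noise_peak_rate)
    spurious peaks are added at uniform m/z; the single precursor sits at
    mass +/- the proton mass depending on mode.
    """
    codebook = fragment_codebook(cfg)
    rng = np.random.default_rng(cfg.seed + 2000)
    adduct = "[M+H]+" if cfg.mode == POSITIVE else "[M-H]-"
    shift = PROTON if cfg.mode == POSITIVE else -PROTON
    spectra = []
    for comp in compounds:
        active = np.flatnonzero(comp.fingerprint)
        base_mzs = codebook[active].ravel()
        for _ in range(cfg.n_spectra_per_compound):
            peaks = [
                Peak(mz, 100.0 * float(np.exp(rng.normal(0.0, cfg.intensity_noise_sd))))
                for mz in base_mzs
            ]
            for _ in range(rng.poisson(cfg.noise_peak_rate)):
                peaks.append(
                    Peak(float(rng.uniform(100.0, 1010.0)), float(rng.uniform(5.0, 100.0)))
                )
            meta = SpectrumMetadata(
                compound_id=comp.compound_id,
                formula=comp.formula,
                inchikey=comp.inchikey,
                precursor_mz=comp.mass + shift,
                adduct=adduct,
                ionization_mode=cfg.mode,
                source="synthetic",
            )
            spectra.append(Spectrum(peaks, meta, precursor_count=1))
    return spectra


def generate_database(
    compounds: list[SyntheticCompound], cfg: SynthConfig
) -> list[CompoundRecord]:
    """True compounds plus ``decoys_per_compound`` decoys each.

    Decoy masses are offset by a ppm value drawn from
    ``decoy_ppm_offset_range`` (random sign), fingerprints differ by exactly
    ``decoy_bit_flips`` flips, and the InChIKey first block always differs
    from the true compound's.
    """
    rng = np.random.default_rng(cfg.seed + 3000)
    records = [
        CompoundRecord(
            compound_id=c.compound_id,
            smiles="",
            inchikey=c.inchikey,
            formula=c.formula,
            monoisotopic_mass=c.mass,
            fingerprint=c.fingerprint.copy(),
        )
        for c in compounds
    ]
    seen_blocks = {c.inchikey[:14] for c in compounds}
    seen_formulas = {c.formula for c in compounds}
    lo, hi = cfg.decoy_ppm_offset_range
    for c in compounds:
        for d in range(cfg.decoys_per_compound):
            ppm = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
            fp = c.fingerprint.copy()
            flip = rng.choice(cfg.n_bits, size=cfg.decoy_bit_flips, replace=False)
            fp[flip] ^= 1
            key = _inchikey_like(rng)
            while key[:14] in seen_blocks:
                key = _inchikey_like(rng)
            seen_blocks.add(key[:14])
            formula = _formula_like(rng)
            while formula in seen_formulas:
                formula = _formula_like(rng)
            seen_formulas.add(formula)
            records.append(
                CompoundRecord(
                    compound_id=f"{c.compound_id}-D{d}",
                    smiles="",
                    inchikey=key,
                    formula=formula,
                    monoisotopic_mass=c.mass * (1.0 + ppm * 1e-6),
                    fingerprint=fp,
                )
            )
    return records


def generate_formula_scores(
    challenges: list[tuple[str, str, list[str]]],
    cfg: SynthConfig,
) -> pd.DataFrame:
    """Emulated external formula-prediction scores.

    ``challenges`` holds (challenge_id, true_formula, candidate_formulas)
    triples.  The true formula's score is drawn from a higher-mean
    distribution than the decoys'; a ``missing_formula_fraction`` of
    challenges omit the true formula entirely (so fusion must fall back to
    fingerprint-only for them).
    """
    rng = np.random.default_rng(cfg.seed + 4000)
    rows = []
    for challenge_id, true_formula, candidate_formulas in challenges:
        drop_true = rng.random() < cfg.missing_formula_fraction
        for formula in candidate_formulas:
            is_true = formula == true_formula
            if is_true and drop_true:
                continue
            mean, sd = (0.9, 0.05) if is_true else (0.4, 0.15)
            rows.append(
                {
                    "challenge_id": challenge_id,
                    "formula": formula,
                    "score": float(np.clip(rng.normal(mean, sd), 0.0, 1.0)),
                }
            )
    return pd.DataFrame(rows, columns=["challenge_id", "formula", "score"])


def _database_frame(records: list[CompoundRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.compound_id for r in records],
            "smiles": [r.smiles for r in records],
            "inchikey": [r.inchikey for r in records],
            "formula": [r.formula for r in records],
            "monoisotopic_mass": [r.monoisotopic_mass for r in records],
            "fingerprint": [
                "".join(map(str, r.fingerprint.tolist())) for r in records
            ],
        }
    )


def generate_dataset(cfg: SynthConfig | None = None, outdir=None) -> dict:
    """Generate a full linked fixture set; optionally write it to disk
    (spectra.msp, compounds.tsv, truth.csv, formula_scores.csv).

    Returns a dict with compounds, spectra, database records, the truth
    table, and the formula-score frame.
    """
    cfg = cfg or SynthConfig()
    compounds = generate_compounds(cfg)
    spectra = generate_spectra(compounds, cfg)
    records = generate_database(compounds, cfg)
    truth = pd.DataFrame(
        {
            "challenge_id": [c.compound_id for c in compounds],
            "inchikey": [c.inchikey for c in compounds],
            "formula": [c.formula for c in compounds],
        }
    )
    by_true: dict[str, list[str]] = {c.compound_id: [] for c in compounds}
    for r in records:
        true_id = r.compound_id.split("-D")[0]
        if true_id in by_true:
            by_true[true_id].append(r.formula)
    challenges = [(c.compound_id, c.formula, by_true[c.compound_id]) for c in compounds]
    formula_scores = generate_formula_scores(challenges, cfg)
    out = {
        "config": cfg,
        "compounds": compounds,
        "spectra": spectra,
        "database": records,
        "truth": truth,
        "formula_scores": formula_scores,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_msp(spectra, outdir / "spectra.msp")
        _database_frame(records).to_csv(outdir / "compounds.tsv", sep="\t", index=False)
        truth.to_csv(outdir / "truth.csv", index=False)
        formula_scores.to_csv(outdir / "formula_scores.csv", index=False)
    return out
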