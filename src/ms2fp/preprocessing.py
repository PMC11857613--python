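"""Spectrum preprocessing: scaling, quality filters, top-peak selection,
fixed-width m/z binning, and bin-occupancy filtering.

The processing pipeline turns a raw peak list into the fixed-length input
vector of the fingerprint-prediction models:

1. scale intensities so the base peak is 100 (relative intensity);
2. drop spectra with no or more than one precursor mass, or fewer than five
   peaks;
3. drop peaks outside 100-1010 Da or with scaled intensity below 1;
4. keep the 20 most intense remaining peaks;
5. sum intensities within 0.01 Da bins (91,001 bins over the closed range);
6. remove bins populated in fewer than 0.1% of the training spectra,
   separately per ionization mode.

Stage order is fixed; each numbered default lives in :class:`PreprocessConfig`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from .spectra_io import Peak, Spectrum

__all__ = [
    "BinGrid",
    "BinnedSpectrum",
    "PreprocessConfig",
    "scale_intensities",
    "spectrum_passes_filters",
    "restrict_peaks",
    "select_top_peaks",
    "bin_index",
    "bin_spectrum",
    "compute_bin_occupancy",
    "filter_bins",
    "preprocess_spectra",
]

logger = logging.getLogger(__name__)

# Guard for float round-off when a peak m/z sits exactly on a bin boundary;
# peak m/z carries ~5 decimals so 1e-7 bins is far below data precision.
_BOUNDARY_EPS = 1e-7


@dataclass(frozen=True)
class BinGrid:
    """Closed m/z grid [mass_low, mass_high] discretized at ``width`` Da.

    With the defaults (100-1010 Da at 0.01 Da) the grid has exactly
    91,001 bins; the upper edge is assigned to the last bin.
    """

    mass_low: float = 100.0
    mass_high: float = 1010.0
    width: float = 0.01

    def __post_init__(self):
        if not (self.mass_high > self.mass_low and self.width > 0):
            raise ValueError("require mass_high > mass_low and width > 0")

    @property
    def n_bins(self) -> int:
        return int(math.floor((self.mass_high - self.mass_low) / self.width + _BOUNDARY_EPS)) + 1


@dataclass
class BinnedSpectrum:
    """Binned intensity vector on a :class:`BinGrid` (stored sparse)."""

    values: sparse.csr_matrix  # shape (1, n_bins)
    grid: BinGrid
    spectrum_ref: str = ""

    def toarray(self) -> np.ndarray:
        return np.asarray(self.values.todense()).ravel()


@dataclass
class PreprocessConfig:
    """Pipeline parameters; the defaults are the standard study conditions."""

    intensity_max: float = 100.0
    min_peaks: int = 5
    top_n_peaks: int = 20
    min_scaled_intensity: float = 1.0
    occupancy_fraction: float = 0.001
    grid: BinGrid = field(default_factory=BinGrid)

    def __post_init__(self):
        if min(self.intensity_max, self.min_peaks, self.top_n_peaks,
               self.min_scaled_intensity) <= 0:
            raise ValueError("all thresholds must be positive")
        if not 0 < self.occupancy_fraction < 1:
            raise ValueError("occupancy_fraction must be in (0, 1)")


def scale_intensities(s: Spectrum, ceiling: float = 100.0) -> Spectrum:
    """Rescale so the most intense peak equals ``ceiling`` (idempotent)."""
    if not s.peaks:
        raise ValueError("cannot scale an empty spectrum")
    peak_max = max(p.intensity for p in s.peaks)
    if peak_max <= 0:
        raise ValueError("cannot scale a spectrum whose intensities are all zero")
    factor = ceiling / peak_max
    return s.with_peaks(Peak(p.mz, p.intensity * factor) for p in s.peaks)


def spectrum_passes_filters(s: Spectrum, cfg: PreprocessConfig) -> bool:
    """Quality filter: exactly one precursor mass and at least ``min_peaks``
    raw peaks."""
    return s.precursor_count == 1 and len(s.peaks) >= cfg.min_peaks


def restrict_peaks(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Keep peaks inside the closed mass range with scaled intensity >= the
    floor.  May return a spectrum with zero peaks; the caller decides whether
    to drop it."""
    grid = cfg.grid
    kept = [
        p
        for p in s.peaks
        if grid.mass_low <= p.mz <= grid.mass_high
        and p.intensity >= cfg.min_scaled_intensity
    ]
    return s.with_peaks(kept)


def select_top_peaks(s: Spectrum, n: int = 20) -> Spectrum:
    """Keep the ``n`` most intense peaks (ties broken toward lower m/z);
    output remains sorted by m/z."""
    if len(s.peaks) <= n:
        return s.with_peaks(s.peaks)
    # peaks are mz-sorted, so a stable sort on -intensity puts the lower-mz
    # member of an intensity tie first
    ranked = sorted(s.peaks, key=lambda p: -p.intensity)
    return s.with_peaks(ranked[:n])


def bin_index(mz: float, grid: BinGrid) -> int:
    """Map an m/z inside the grid to its bin: floor((mz - low)/width), with
    the closed upper edge assigned to the last bin."""
    if not grid.mass_low <= mz <= grid.mass_high:
        raise ValueError(f"m/z {mz} outside grid [{grid.mass_low}, {grid.mass_high}]")
    idx = int(math.floor((mz - grid.mass_low) / grid.width + _BOUNDARY_EPS))
    return min(idx, grid.n_bins - 1)


def bin_spectrum(s: Spectrum, grid: BinGrid | None = None) -> BinnedSpectrum:
    """Sum peak intensities within each bin; total intensity is conserved."""
    grid = grid or BinGrid()
    if s.peaks:
        idx = np.array([bin_index(p.mz, grid) for p in s.peaks])
        vals = np.array([p.intensity for p in s.peaks], dtype=float)
        mat = sparse.csr_matrix(
            (vals, (np.zeros_like(idx), idx)), shape=(1, grid.n_bins)
        )
        mat.sum_duplicates()
    else:
        mat = sparse.csr_matrix((1, grid.n_bins))
    return BinnedSpectrum(mat, grid, s.metadata.compound_id)


def compute_bin_occupancy(binned: Sequence[BinnedSpectrum] | sparse.spmatrix) -> np.ndarray:
    """Fraction of spectra with a nonzero intensity in each bin."""
    if sparse.issparse(binned):
        mat = binned.tocsr()
    else:
        binned = list(binned)
        if not binned:
            raise ValueError("occupancy of an empty spectrum collection is undefined")
        mat = sparse.vstack([b.values for b in binned]).tocsr()
    if mat.shape[0] == 0:
        raise ValueError("occupancy of an empty spectrum collection is undefined")
    nonzero_per_bin = (mat != 0).sum(axis=0)
    return np.asarray(nonzero_per_bin).ravel() / mat.shape[0]


def filter_bins(occupancy: np.ndarray, fraction: float = 0.001) -> np.ndarray:
    """Retained bin indices: occupancy strictly below ``fraction`` is
    removed, so a bin at exactly the threshold survives."""
    retained = np.flatnonzero(np.asarray(occupancy) >= fraction)
    if retained.size == 0:
        logger.warning("bin-occupancy filter retained no bins")
    return retained


def preprocess_spectra(
    spectra: Iterable[Spectrum],
    cfg: PreprocessConfig | None = None,
    retained_bins: np.ndarray | None = None,
):
    """Run the full pipeline over a spectrum collection.

    Returns ``(X, retained_bins, kept_spectra)`` where ``X`` is a sparse
    (n_spectra x n_retained_bins) matrix of binned intensities restricted to
    the retained bins.  When ``retained_bins`` is given (applying a trained
    model to new spectra) the occupancy filter is skipped and the provided
    bin set is used; otherwise occupancy is computed from this collection.
    Mode separation is the caller's responsibility: pass one mode at a time.
    """
    cfg = cfg or PreprocessConfig()
    kept_spectra: list[Spectrum] = []
    rows = []
    for s in spectra:
        s = scale_intensities(s, cfg.intensity_max)
        if not spectrum_passes_filters(s, cfg):
            continue
        s = restrict_peaks(s, cfg)
        if not s.peaks:
            continue
        s = select_top_peaks(s, cfg.top_n_peaks)
        rows.append(bin_spectrum(s, cfg.grid).values)
        kept_spectra.append(s)
    if not rows:
        raise ValueError("no spectra survived preprocessing")
    mat = sparse.vstack(rows).tocsr()
    if retained_bins is None:
        occupancy = compute_bin_occupancy(mat)
        retained_bins = filter_bins(occupancy, cfg.occupancy_fraction)
    retained_bins = np.asarray(retained_bins, dtype=int)
    return mat[:, retained_bins], retained_bins, kept_spectra
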