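"""Reading and writing annotated MS/MS spectra in MSP and MGF dialects.

Spectral libraries come in several loosely standardized text dialects.  This
module parses NIST-style and MoNA-style MSP (``Key: value`` headers followed
by ``Num Peaks`` and a peak table) and Mascot generic format (``BEGIN IONS``
blocks with ``KEY=value`` headers), keeping enough raw-record information —
in particular the *number* of precursor-mass fields actually present — for
downstream quality filters that reject spectra with no, or more than one,
precursor mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Peak",
    "SpectrumMetadata",
    "Spectrum",
    "SpectrumParseError",
    "read_msp",
    "read_mgf",
    "write_msp",
    "write_mgf",
]

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$", re.IGNORECASE)

POSITIVE = "positive"
NEGATIVE = "negative"


class SpectrumParseError(ValueError):
    """Malformed spectral record; carries the 0-based record/block index."""

    def __init__(self, message: str, record_index: int):
        super().__init__(f"record {record_index}: {message}")
        self.record_index = record_index


@dataclass(frozen=True)
class Peak:
    """A single fragment peak: m/z in Da (> 0), intensity >= 0."""

    mz: float
    intensity: float

    def __post_init__(self):
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass
class SpectrumMetadata:
    """Reference-compound and instrument annotations attached to a spectrum."""

    compound_id: str = ""
    formula: str = ""
    inchikey: str | None = None
    smiles: str | None = None
    precursor_mz: float | None = None
    adduct: str = ""
    ionization_mode: str = POSITIVE
    collision_energy: str = ""
    source: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ionization_mode not in (POSITIVE, NEGATIVE):
            raise ValueError(
                f"ionization_mode must be '{POSITIVE}' or '{NEGATIVE}', "
                f"got {self.ionization_mode!r}"
            )
        if self.inchikey is not None and not _INCHIKEY_RE.match(self.inchikey):
            raise ValueError(f"malformed InChIKey: {self.inchikey!r}")


@dataclass
class Spectrum:
    """An MS/MS spectrum: peaks sorted ascending by m/z plus metadata.

    ``precursor_count`` records how many precursor-mass values the raw
    record carried (0, 1, or more); it is *not* defaulted to 1, so the
    one-precursor quality filter can be applied faithfully.
    """

    peaks: list[Peak]
    metadata: SpectrumMetadata
    precursor_count: int = 1

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        if self.precursor_count < 0:
            raise ValueError("precursor_count must be >= 0")

    @property
    def mz(self):
        return [p.mz for p in self.peaks]

    @property
    def intensities(self):
        return [p.intensity for p in self.peaks]

    def with_peaks(self, peaks: Iterable[Peak]) -> "Spectrum":
        return Spectrum(list(peaks), replace(self.metadata), self.precursor_count)


# --- key normalization ------------------------------------------------------

# Canonical metadata field <- lowercase header aliases seen across NIST-style,
# MoNA-style MSP and common MGF exports.
_FIELD_ALIASES = {
    "compound_id": {"name", "title", "compound_name", "db#", "id"},
    "formula": {"formula", "molecular_formula", "molecularformula"},
    "inchikey": {"inchikey", "inchi_key"},
    "smiles": {"smiles", "canonical_smiles"},
    "adduct": {"precursor_type", "precursortype", "adduct", "ion_type"},
    "ionization_mode": {"ion_mode", "ionmode", "ionization_mode", "ionization mode"},
    "collision_energy": {"collision_energy", "collisionenergy", "ce"},
    "source": {"source", "library", "instrument"},
}
_PRECURSOR_KEYS = {"precursormz", "precursor_mz", "precursor m/z", "pepmass"}
_ALIAS_TO_FIELD = {
    alias: fld for fld, aliases in _FIELD_ALIASES.items() for alias in aliases
}


def _norm_key(key: str) -> str:
    return key.strip().lower().replace("-", "_").replace(" ", "_")


def _parse_mode(raw: str) -> str:
    raw = raw.strip().lower()
    if raw in {"p", "positive", "+", "pos", "1+", "2+"}:
        return POSITIVE
    if raw in {"n", "negative", "-", "neg", "1-", "2-"}:
        return NEGATIVE
    raise ValueError(f"unrecognized ionization mode {raw!r}")


def _floats_in(text: str) -> list[float]:
    return [float(tok) for tok in re.split(r"[,\s]+", text.strip()) if tok]


def _build_spectrum(
    headers: list[tuple[str, str]],
    peak_lines: list[str],
    record_index: int,
    n_peaks_declared: int | None,
    default_mode: str | None = None,
) -> Spectrum:
    meta_kwargs: dict = {"extra": {}}
    precursor_values: list[float] = []
    mode: str | None = default_mode

    for key, value in headers:
        nkey = _norm_key(key)
        if nkey in _PRECURSOR_KEYS:
            try:
                vals = _floats_in(value)
            except ValueError:
                raise SpectrumParseError(
                    f"unparsable precursor value {value!r}", record_index
                )
            # MGF PEPMASS may carry a precursor intensity as 2nd token.
            if nkey == "pepmass" and len(vals) == 2:
                vals = vals[:1]
            precursor_values.extend(vals)
        elif nkey in _ALIAS_TO_FIELD:
            fld = _ALIAS_TO_FIELD[nkey]
            if fld == "ionization_mode":
                try:
                    mode = _parse_mode(value)
                except ValueError as exc:
                    raise SpectrumParseError(str(exc), record_index)
            else:
                meta_kwargs.setdefault(fld, value.strip())
        elif nkey == "charge":
            # MGF charge strings like 1+, 2-; used for mode only if no
            # explicit ion-mode field appears.
            if mode is None or mode == default_mode:
                try:
                    mode = _parse_mode(value)
                except ValueError:
                    pass
        elif nkey != "num_peaks":
            meta_kwargs["extra"][key.strip()] = value.strip()

    if n_peaks_declared is not None and n_peaks_declared != len(peak_lines):
        raise SpectrumParseError(
            f"declared {n_peaks_declared} peaks but found {len(peak_lines)}",
            record_index,
        )

    peaks = []
    for line in peak_lines:
        toks = re.split(r"[\s,;]+", line.strip())
        if len(toks) < 2:
            raise SpectrumParseError(f"unparsable peak line {line!r}", record_index)
        try:
            peaks.append(Peak(float(toks[0]), float(toks[1])))
        except ValueError as exc:
            raise SpectrumParseError(
                f"unparsable peak line {line!r} ({exc})", record_index
            )

    ik = meta_kwargs.get("inchikey")
    if ik is not None and not _INCHIKEY_RE.match(ik):
        # Tolerate junk annotations rather than losing the record.
        meta_kwargs["extra"]["InChIKey_raw"] = meta_kwargs.pop("inchikey")

    meta = SpectrumMetadata(
        ionization_mode=mode or POSITIVE,
        precursor_mz=precursor_values[0] if len(precursor_values) == 1 else None,
        **meta_kwargs,
    )
    return Spectrum(peaks, meta, precursor_count=len(precursor_values))


# --- MSP --------------------------------------------------------------------

_HEADER_RE = re.compile(r"^([^:]+):\s*(.*)$")
_PEAK_LINE_RE = re.compile(r"^\s*\d")


def _msp_records(lines: Iterable[str]):
    """Split MSP text into records on blank lines / new Name headers."""
    current: list[str] = []
    for line in lines:
        if not line.strip():
            if current:
                yield current
                current = []
            continue
        if _norm_key(line.split(":")[0]) == "name" and current and any(
            _PEAK_LINE_RE.match(l) for l in current
        ):
            yield current
            current = []
        current.append(line.rstrip("\n"))
    if current:
        yield current


def read_msp(path, on_error: str = "raise") -> list[Spectrum]:
    """Parse an MSP spectral library.

    Parameters
    ----------
    path : str or Path
        MSP text file (NIST ``Name:`` or MoNA ``NAME:`` header style;
        space- or tab-separated peak lines).
    on_error : {"raise", "skip"}
        Whether a malformed record aborts parsing or is dropped.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    spectra: list[Spectrum] = []
    with open(path) as fh:
        for idx, record in enumerate(_msp_records(fh)):
            try:
                headers: list[tuple[str, str]] = []
                peak_lines: list[str] = []
                n_declared = None
                in_peaks = False
                for line in record:
                    m = _HEADER_RE.match(line)
                    if not in_peaks and m and not _PEAK_LINE_RE.match(line):
                        key, value = m.group(1), m.group(2)
                        if _norm_key(key) == "num_peaks":
                            n_declared = int(value)
                            in_peaks = True
                        else:
                            headers.append((key, value))
                    else:
                        in_peaks = True
                        peak_lines.append(line)
                spectra.append(
                    _build_spectrum(headers, peak_lines, idx, n_declared)
                )
            except SpectrumParseError:
                if on_error == "raise":
                    raise
    return spectra


def write_msp(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra as NIST-style MSP (m/z to 5 decimals, intensity to 4
    significant figures); optional metadata fields are omitted when unset."""
    with open(path, "w") as fh:
        for s in spectra:
            m = s.metadata
            fh.write(f"Name: {m.compound_id}\n")
            if m.formula:
                fh.write(f"Formula: {m.formula}\n")
            if m.inchikey:
                fh.write(f"InChIKey: {m.inchikey}\n")
            if m.smiles:
                fh.write(f"SMILES: {m.smiles}\n")
            if m.precursor_mz is not None:
                fh.write(f"PrecursorMZ: {m.precursor_mz:.5f}\n")
            if m.adduct:
                fh.write(f"Precursor_type: {m.adduct}\n")
            fh.write(f"Ion_mode: {'P' if m.ionization_mode == POSITIVE else 'N'}\n")
            if m.collision_energy:
                fh.write(f"Collision_energy: {m.collision_energy}\n")
            if m.source:
                fh.write(f"Source: {m.source}\n")
            for key, value in m.extra.items():
                fh.write(f"{key}: {value}\n")
            fh.write(f"Num Peaks: {len(s.peaks)}\n")
            for p in s.peaks:
                fh.write(f"{p.mz:.5f} {p.intensity:.4g}\n")
            fh.write("\n")


# --- MGF --------------------------------------------------------------------


def read_mgf(path, on_error: str = "raise") -> list[Spectrum]:
    """Parse a Mascot generic format file (BEGIN IONS / END IONS blocks)."""
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    spectra: list[Spectrum] = []
    block: list[str] | None = None
    idx = 0
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.upper() == "BEGIN IONS":
                if block is not None:
                    err = SpectrumParseError("missing END IONS", idx)
                    if on_error == "raise":
                        raise err
                    block = None
                block = []
                continue
            if stripped.upper() == "END IONS":
                if block is None:
                    err = SpectrumParseError("END IONS without BEGIN IONS", idx)
                    if on_error == "raise":
                        raise err
                    continue
                try:
                    spectra.append(_parse_mgf_block(block, idx))
                except SpectrumParseError:
                    if on_error == "raise":
                        raise
                block = None
                idx += 1
                continue
            if block is not None and stripped:
                block.append(stripped)
    if block is not None:
        err = SpectrumParseError("missing END IONS", idx)
        if on_error == "raise":
            raise err
    return spectra


def _parse_mgf_block(block: list[str], idx: int) -> Spectrum:
    headers: list[tuple[str, str]] = []
    peak_lines: list[str] = []
    for line in block:
        if "=" in line and not _PEAK_LINE_RE.match(line):
            key, _, value = line.partition("=")
            headers.append((key, value))
        else:
            peak_lines.append(line)
    return _build_spectrum(headers, peak_lines, idx, None)


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra as MGF blocks (same numeric precision as write_msp)."""
    with open(path, "w") as fh:
        for s in spectra:
            m = s.metadata
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={m.compound_id}\n")
            if m.precursor_mz is not None:
                fh.write(f"PEPMASS={m.precursor_mz:.5f}\n")
            fh.write(f"IONMODE={m.ionization_mode}\n")
            if m.adduct:
                fh.write(f"ADDUCT={m.adduct}\n")
            if m.formula:
                fh.write(f"FORMULA={m.formula}\n")
            if m.inchikey:
                fh.write(f"INCHIKEY={m.inchikey}\n")
            if m.smiles:
                fh.write(f"SMILES={m.smiles}\n")
            if m.collision_energy:
                fh.write(f"COLLISIONENERGY={m.collision_energy}\n")
            if m.source:
                fh.write(f"SOURCE={m.source}\n")
            for p in s.peaks:
                fh.write(f"{p.mz:.5f} {p.intensity:.4g}\n")
            fh.write("END IONS\n\n")
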