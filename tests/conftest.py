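import numpy as np
import pytest

from ms2fp.spectra_io import Peak, Spectrum, SpectrumMetadata


@pytest.fixture
def two_record_msp(tmp_path):
    """A 2-record MSP fixture with 5 and 7 peaks, mixed header dialects."""
    text = """\
Name: alpha
Formula: C6H12O6
InChIKey: WQZGKKKJIJFFOK-GASJEMHNSA-N
PrecursorMZ: 181.07066
Precursor_type: [M+H]+
Ion_mode: P
Num Peaks: 5
101.0 10
120.5 50.5
150.25 100
161.1 20
170.0\t5

NAME: beta
FORMULA: C9H11NO2
ION MODE: N
PRECURSORMZ: 164.07170
Num Peaks: 7
103.05 12
110.1 30
115.0 5
119.0 99
131.3 45
140.0 80
147.11 60
"""
    path = tmp_path / "two.msp"
    path.write_text(text)
    return path


def make_spectrum(peaks, mode="positive", precursor=200.0, precursor_count=1,
                  compound_id="cmpd", inchikey=None):
    return Spectrum(
        [Peak(mz, inten) for mz, inten in peaks],
        SpectrumMetadata(
            compound_id=compound_id,
            precursor_mz=precursor,
            ionization_mode=mode,
            inchikey=inchikey,
        ),
        precursor_count=precursor_count,
    )


@pytest.fixture
def simple_spectrum():
    return make_spectrum([(150.0, 2.0), (200.0, 4.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
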