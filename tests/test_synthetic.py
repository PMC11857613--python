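"""Synthetic generator: determinism, planted-rule structure, decoy design."""

import numpy as np
import pytest

from ms2fp.preprocessing import BinGrid, bin_index
from ms2fp.spectra_io import read_msp
from ms2fp.synthetic import (
    SynthConfig,
    fragment_codebook,
    generate_compounds,
    generate_database,
    generate_dataset,
    generate_formula_scores,
    generate_spectra,
)


@pytest.fixture(scope="module")
def cfg():
    return SynthConfig(seed=7)


@pytest.fixture(scope="module")
def compounds(cfg):
    return generate_compounds(cfg)


class TestCompounds:
    def test_deterministic(self, cfg, compounds):
        again = generate_compounds(cfg)
        assert [c.inchikey for c in again] == [c.inchikey for c in compounds]
        assert all(
            np.array_equal(a.fingerprint, b.fingerprint)
            for a, b in zip(again, compounds)
        )

    def test_identifiers_unique_and_inchikey_like(self, compounds):
        keys = [c.inchikey for c in compounds]
        assert len(set(k[:14] for k in keys)) == len(keys)
        assert all(len(k) == 27 and k[14] == "-" and k[25] == "-" for k in keys)

    def test_masses_in_range(self, compounds):
        assert all(150.0 <= c.mass <= 900.0 for c in compounds)

    def test_mean_activity_within_three_se(self):
        big = SynthConfig(n_compounds=1000, seed=11)
        comps = generate_compounds(big)
        k = np.array([c.fingerprint.sum() for c in comps])
        p = big.bits_per_compound / big.n_bits
        se = np.sqrt(big.n_bits * p * (1 - p) / len(comps))
        # at-least-one-bit correction only lifts the mean, tolerate upward
        assert abs(k.mean() - big.bits_per_compound) < 3 * se + 0.05


class TestSpectra:
    def test_noiseless_replicates_identical(self, cfg, compounds):
        spectra = generate_spectra(compounds[:3], cfg)
        per = cfg.n_spectra_per_compound
        first, second = spectra[0], spectra[1]
        assert first.mz == second.mz
        assert first.intensities == second.intensities
        assert len(spectra) == 3 * per

    def test_peak_count_matches_active_bits(self, cfg, compounds):
        spectra = generate_spectra(compounds, cfg)
        for comp, s in zip(compounds, spectra[:: cfg.n_spectra_per_compound]):
            assert len(s.peaks) == comp.fingerprint.sum() * cfg.peaks_per_bit

    def test_single_precursor_and_filters(self, cfg, compounds):
        spectra = generate_spectra(compounds, cfg)
        assert all(s.precursor_count == 1 for s in spectra)
        assert all(s.metadata.precursor_mz is not None for s in spectra)

    def test_codebook_bins_distinct_and_in_range(self, cfg):
        code = fragment_codebook(cfg)
        grid = BinGrid()
        bins = [bin_index(mz, grid) for mz in code.ravel()]
        assert len(set(bins)) == len(bins)

    def test_msp_round_trip(self, cfg, compounds, tmp_path):
        from ms2fp.spectra_io import write_msp

        spectra = generate_spectra(compounds[:5], cfg)
        path = tmp_path / "synth.msp"
        write_msp(spectra, path)
        back = read_msp(path)
        assert len(back) == len(spectra)
        assert back[0].mz == pytest.approx(spectra[0].mz, abs=1e-5)
        assert back[0].metadata.inchikey == spectra[0].metadata.inchikey


class TestDatabase:
    def test_decoy_count_and_hamming_distance(self, cfg, compounds):
        records = generate_database(compounds, cfg)
        assert len(records) == len(compounds) * (1 + cfg.decoys_per_compound)
        by_id = {r.compound_id: r for r in records}
        for comp in compounds:
            for d in range(cfg.decoys_per_compound):
                decoy = by_id[f"{comp.compound_id}-D{d}"]
                dist = int(np.sum(decoy.fingerprint != comp.fingerprint))
                assert dist == cfg.decoy_bit_flips
                assert decoy.inchikey[:14] != comp.inchikey[:14]

    def test_decoy_ppm_offsets_in_configured_range(self, cfg, compounds):
        records = generate_database(compounds, cfg)
        lo, hi = cfg.decoy_ppm_offset_range
        for comp in compounds:
            for r in records:
                if r.compound_id.startswith(comp.compound_id + "-D"):
                    ppm = abs(r.monoisotopic_mass - comp.mass) / comp.mass * 1e6
                    assert lo - 1e-6 <= ppm <= hi + 1e-6

    def test_offsets_beyond_tolerance_leave_only_truth(self, compounds):
        from ms2fp.annotate import retrieve_candidates

        far = SynthConfig(seed=7, decoy_ppm_offset_range=(8.0, 20.0))
        records = generate_database(compounds, far)
        comp = compounds[0]
        got = retrieve_candidates(comp.mass + 1.007276, "positive", records)
        ids = {c.record.compound_id for c in got}
        decoys_of_comp = {f"{comp.compound_id}-D{d}" for d in range(far.decoys_per_compound)}
        assert comp.compound_id in ids
        assert ids & decoys_of_comp == set()

    def test_close_offsets_make_decoys_retrievable(self, compounds):
        from ms2fp.annotate import retrieve_candidates

        near = SynthConfig(seed=7, decoy_ppm_offset_range=(0.5, 3.0))
        records = generate_database(compounds, near)
        comp = compounds[0]
        got = retrieve_candidates(comp.mass + 1.007276, "positive", records)
        ids = {c.record.compound_id for c in got}
        assert comp.compound_id in ids
        assert any(i.startswith(comp.compound_id + "-D") for i in ids)


class TestFormulaScores:
    def _challenges(self, compounds, cfg):
        records = generate_database(compounds, cfg)
        by_true = {}
        for r in records:
            true_id = r.compound_id.split("-D")[0]
            by_true.setdefault(true_id, []).append(r.formula)
        return [(c.compound_id, c.formula, by_true[c.compound_id]) for c in compounds]

    def test_every_challenge_has_true_row_when_fraction_zero(self, cfg, compounds):
        df = generate_formula_scores(self._challenges(compounds, cfg), cfg)
        truth = {c.compound_id: c.formula for c in compounds}
        for cid, formula in truth.items():
            sub = df[df.challenge_id == cid]
            assert formula in set(sub.formula)

    def test_missing_fraction_one_removes_all_true_rows(self, compounds):
        cfg = SynthConfig(seed=7, missing_formula_fraction=1.0)
        df = generate_formula_scores(self._challenges(compounds, cfg), cfg)
        truth = {c.compound_id: c.formula for c in compounds}
        for cid, formula in truth.items():
            assert formula not in set(df[df.challenge_id == cid].formula)

    def test_true_scores_higher_on_average(self, cfg, compounds):
        df = generate_formula_scores(self._challenges(compounds, cfg), cfg)
        truth = {c.compound_id: c.formula for c in compounds}
        is_true = df.apply(lambda r: truth[r.challenge_id] == r.formula, axis=1)
        assert df[is_true].score.mean() > df[~is_true].score.mean() + 0.2

    def test_deterministic(self, cfg, compounds):
        ch = self._challenges(compounds, cfg)
        a = generate_formula_scores(ch, cfg)
        b = generate_formula_scores(ch, cfg)
        assert a.equals(b)


def test_generate_dataset_writes_linked_files(tmp_path):
    out = generate_dataset(SynthConfig(seed=2, n_compounds=10), outdir=tmp_path)
    assert (tmp_path / "spectra.msp").exists()
    assert (tmp_path / "compounds.tsv").exists()
    assert (tmp_path / "truth.csv").exists()
    assert (tmp_path / "formula_scores.csv").exists()
    spectra = read_msp(tmp_path / "spectra.msp")
    assert len(spectra) == len(out["spectra"])
    import pandas as pd

    db = pd.read_csv(tmp_path / "compounds.tsv", sep="\t")
    assert len(db) == len(out["database"])
    assert set(out["truth"].challenge_id) <= set(db.id)
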