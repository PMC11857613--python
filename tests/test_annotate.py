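"""Adduct arithmetic, candidate retrieval, score fusion, and ranking."""

import numpy as np
import pytest

from ms2fp.annotate import (
    ADDUCTS,
    CompoundRecord,
    RetrievalConfig,
    ScoredCandidate,
    combine_scores,
    fingerprint_score,
    minmax_normalize,
    neutral_mass,
    random_baseline,
    rank_candidates,
    retrieve_candidates,
    score_and_rank,
)


def record(cid, mass, inchikey=None, formula="C6H12O6", fp=None):
    return CompoundRecord(
        compound_id=cid,
        smiles="",
        inchikey=inchikey or ("A" * 14 + "-" + "B" * 10 + "-N"),
        formula=formula,
        monoisotopic_mass=mass,
        fingerprint=fp,
    )


class TestNeutralMass:
    def test_protonated_glucose(self):
        # glucose M = 180.063389; [M+H]+ measured at 181.070665
        assert neutral_mass(181.070665, "[M+H]+") == pytest.approx(180.063389, abs=1e-6)

    def test_deprotonated_matches_same_neutral(self):
        assert neutral_mass(179.056113, "[M-H]-") == pytest.approx(180.063389, abs=1e-6)

    def test_round_trip_all_adducts(self):
        for adduct, (_, shift) in ADDUCTS.items():
            mz = 250.1234
            assert neutral_mass(mz, adduct) + shift == pytest.approx(mz, abs=1e-12)

    def test_unknown_adduct(self):
        with pytest.raises(ValueError):
            neutral_mass(100.0, "[M+X]+")


class TestRetrieval:
    def test_five_ppm_window(self):
        db = [
            record("a", 180.063388),
            record("b", 180.065000),  # ~9 ppm away
            record("c", 342.116212),
        ]
        got = retrieve_candidates(181.070664, "positive", db)
        assert [c.record.compound_id for c in got] == ["a"]

    def test_wider_tolerance_recovers_neighbor(self):
        db = [record("a", 180.063388), record("b", 180.065000), record("c", 342.116212)]
        got = retrieve_candidates(
            181.070664, "positive", db, RetrievalConfig(ppm_tolerance=20)
        )
        assert {c.record.compound_id for c in got} == {"a", "b"}

    def test_far_query_empty(self):
        db = [record("a", 180.063388)]
        assert retrieve_candidates(500.0, "positive", db) == []

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            retrieve_candidates(181.07, "positive", [])

    def test_multi_adduct_match_appears_once_with_both_tags(self):
        # one compound whose mass matches the query under [M+H]+ and another
        # adduct: engineer masses so M+H and M+Na windows hit the same record
        mz = 250.0
        m_h = neutral_mass(mz, "[M+H]+")
        db = [record("a", m_h), record("b", neutral_mass(mz, "[M+Na]+"))]
        got = retrieve_candidates(mz, "positive", db)
        assert len(got) == 2
        tags = {c.record.compound_id: c.adducts for c in got}
        assert tags["a"] == ["[M+H]+"]
        assert tags["b"] == ["[M+Na]+"]

    def test_equals_brute_force_scan_and_monotone(self, rng):
        """Windowed retrieval equals a linear scan on 100 random toy
        databases; widening the tolerance never removes candidates."""
        for _ in range(100):
            db = [
                record(f"c{i}", float(rng.uniform(100, 900)))
                for i in range(int(rng.integers(5, 40)))
            ]
            # place some records deliberately close to a query-implied mass
            mz = float(rng.uniform(150, 800))
            for i in range(3):
                ppm = rng.uniform(-15, 15)
                m = neutral_mass(mz, "[M+H]+") * (1 + ppm * 1e-6)
                if m > 0:
                    db.append(record(f"near{i}", m))
            for tol in (5.0, 20.0):
                cfg = RetrievalConfig(ppm_tolerance=tol)
                got = {c.record.compound_id for c in
                       retrieve_candidates(mz, "positive", db, cfg)}
                brute = set()
                for r in db:
                    for adduct in ("[M+H]+", "[M+NH4]+", "[M+Na]+"):
                        m = neutral_mass(mz, adduct)
                        if abs(r.monoisotopic_mass - m) / m <= tol * 1e-6:
                            brute.add(r.compound_id)
                assert got == brute
            narrow = {c.record.compound_id for c in
                      retrieve_candidates(mz, "positive", db,
                                          RetrievalConfig(ppm_tolerance=5))}
            wide = {c.record.compound_id for c in
                    retrieve_candidates(mz, "positive", db,
                                        RetrievalConfig(ppm_tolerance=20))}
            assert narrow <= wide


class TestScores:
    def test_fingerprint_score_identity_and_disjoint(self):
        assert fingerprint_score(np.array([1, 1, 0]), np.array([1, 1, 0])) == 1.0
        assert fingerprint_score(np.array([1, 0, 0]), np.array([0, 1, 1])) == 0.0

    def test_fingerprint_score_hand_value(self):
        # binarized [1,1,0,0] vs [1,0,1,0]: TP=1, FP=1, FN=1
        got = fingerprint_score(np.array([0.9, 0.8, 0.1, 0.2]),
                                np.array([1, 0, 1, 0]))
        assert got == pytest.approx(1 / 3)

    def test_probability_space_soft_form(self):
        p = np.array([0.5, 0.5])
        y = np.array([1.0, 0.0])
        got = fingerprint_score(p, y, space="probability")
        assert got == pytest.approx(0.5 / 1.5)

    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([2, 4, 6], [0, 0.5, 1]),
            ([5], [1.0]),
            ([-3, 0, 3, 9], [0, 0.25, 0.5, 1]),
            ([7, 7, 7], [1, 1, 1]),
        ],
    )
    def test_minmax(self, scores, expected):
        assert minmax_normalize(scores) == pytest.approx(expected)

    def test_minmax_empty_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize([])

    def test_combine(self):
        assert combine_scores(0.8, 0.2) == pytest.approx(0.62)
        assert combine_scores(0.5, None) == 0.5
        assert combine_scores(1.0, 1.0) == 1.0

    def test_overall_monotone_in_each_component(self):
        assert combine_scores(0.9, 0.5) > combine_scores(0.8, 0.5)
        assert combine_scores(0.8, 0.6) > combine_scores(0.8, 0.5)


class TestRanking:
    def _cands(self, scores):
        out = []
        for i, s in enumerate(scores):
            c = ScoredCandidate(record(f"c{i}", 100.0 + i), ["[M+H]+"])
            c.overall_score = s
            out.append(c)
        return out

    def test_simple_order(self):
        ranked = rank_candidates(self._cands([0.9, 0.2, 0.7]))
        assert [(c.record.compound_id, c.rank) for c in ranked] == [
            ("c0", 1), ("c2", 2), ("c1", 3)
        ]

    def test_pessimistic_ties(self):
        ranked = rank_candidates(self._cands([0.8, 0.8, 0.1]))
        assert [c.rank for c in ranked] == [2, 2, 3]

    def test_single_candidate(self):
        assert rank_candidates(self._cands([0.4]))[0].rank == 1

    def test_score_and_rank_fuses_formula_scores(self):
        cands = [
            ScoredCandidate(record("a", 100.0, formula="CH4"), ["[M+H]+"]),
            ScoredCandidate(record("b", 100.0, formula="NH3"), ["[M+H]+"]),
            ScoredCandidate(record("c", 100.0, formula="H2O"), ["[M+H]+"]),
        ]
        predicted = np.array([1.0, 0.0, 1.0, 0.0])
        fps = [np.array([1, 0, 1, 0]), np.array([1, 0, 1, 0]), np.array([1, 1, 0, 0])]
        ranked = score_and_rank(cands, predicted, fps, {"CH4": 2.0, "NH3": 8.0})
        by_id = {c.record.compound_id: c for c in ranked}
        assert by_id["a"].fingerprint_score == 1.0
        assert by_id["a"].formula_score_norm == 0.0
        assert by_id["b"].formula_score_norm == 1.0
        assert by_id["a"].overall_score == pytest.approx(0.7)
        assert by_id["b"].overall_score == pytest.approx(0.7 + 0.3)
        # c has no formula score: fingerprint-only rule
        assert by_id["c"].formula_score_norm is None
        assert by_id["c"].overall_score == by_id["c"].fingerprint_score


class TestRandomBaseline:
    def test_ten_candidates_top1_near_tenth(self):
        lists = [([f"c{i}" for i in range(10)], "c3") for _ in range(50)]
        got = random_baseline(lists, n_shuffles=100, ks=(1,), seed=0)
        se = np.sqrt(0.1 * 0.9 / (100 * 50))
        assert abs(got[1] - 0.1) < 3 * se + 0.01

    def test_k_at_least_list_size_is_one(self):
        lists = [(["a", "b", "c"], "b")]
        got = random_baseline(lists, n_shuffles=20, ks=(3, 10), seed=1)
        assert got[3] == 1.0 and got[10] == 1.0

    def test_deterministic_under_seed(self):
        lists = [([f"c{i}" for i in range(7)], "c2") for _ in range(5)]
        a = random_baseline(lists, seed=9)
        b = random_baseline(lists, seed=9)
        assert a == b

    def test_missing_true_compound_counts_as_miss(self):
        lists = [(["a", "b"], "z")]
        got = random_baseline(lists, n_shuffles=10, ks=(1, 2), seed=0)
        assert got[1] == 0.0 and got[2] == 0.0
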