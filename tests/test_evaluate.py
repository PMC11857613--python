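"""Metric definitions, their oracle equivalence, hit rule, and top-k tables."""

import math

import numpy as np
import pytest

from ms2fp.evaluate import (
    MetricCounts,
    confusion,
    f1,
    group_kfold,
    is_hit,
    mcc,
    structure_disjoint_filter,
    tanimoto,
    topk_table,
)

from .conftest import make_spectrum


class TestConfusion:
    @pytest.mark.parametrize(
        "pred,truth,expected",
        [
            ([1, 0, 1], [1, 0, 1], (2, 0, 0, 1)),
            ([1, 1, 0, 0], [1, 0, 1, 0], (1, 1, 1, 1)),
            ([0, 0, 0, 0], [1, 1, 1, 1], (0, 0, 4, 0)),
        ],
    )
    def test_counts(self, pred, truth, expected):
        c = confusion(pred, truth)
        assert (c.TP, c.FP, c.FN, c.TN) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestScalarMetrics:
    def test_tanimoto_hand_values(self):
        assert tanimoto(MetricCounts(1, 1, 1, 0)) == pytest.approx(1 / 3)
        assert tanimoto(MetricCounts(3, 0, 0, 2)) == 1.0
        assert tanimoto(MetricCounts(0, 2, 1, 0)) == 0.0
        assert tanimoto(MetricCounts(0, 0, 0, 5)) == 1.0  # all-negative convention

    def test_printed_denominator_variant_leaves_unit_interval(self):
        # TP=3, FP=1, FN=1: standard 3/5; the printed form 3/(1+1-3) = -3
        assert tanimoto(MetricCounts(3, 1, 1, 0), denominator="printed") == -3.0

    def test_f1_hand_values(self):
        assert f1(MetricCounts(1, 1, 1, 0)) == pytest.approx(0.5)
        assert f1(MetricCounts(4, 0, 0, 3)) == 1.0
        assert f1(MetricCounts(0, 2, 0, 1)) == 0.0
        assert f1(MetricCounts(0, 0, 0, 3)) == 1.0

    def test_mcc_hand_values(self):
        assert mcc(MetricCounts(1, 1, 1, 1)) == 0.0
        assert mcc(MetricCounts(2, 0, 0, 2)) == 1.0
        assert mcc(MetricCounts(0, 2, 2, 0)) == -1.0
        assert mcc(MetricCounts(3, 0, 0, 0)) == 0.0  # empty marginal convention

    def test_oracle_equivalence_on_random_pairs(self, rng):
        """tanimoto/f1/mcc from counts match brute-force recomputation from
        raw vectors, and F1 = 2T/(1+T) holds."""
        for _ in range(1000):
            n = int(rng.integers(4, 60))
            pred = rng.random(n) < rng.uniform(0.1, 0.9)
            truth = rng.random(n) < rng.uniform(0.1, 0.9)
            c = confusion(pred, truth)
            tp = int(np.sum(pred & truth))
            fp = int(np.sum(pred & ~truth))
            fn = int(np.sum(~pred & truth))
            tn = n - tp - fp - fn
            t_brute = tp / (tp + fp + fn) if tp + fp + fn else 1.0
            if tp == 0:
                f_brute = 1.0 if fp == 0 and fn == 0 else 0.0
            else:
                p_, r_ = tp / (tp + fp), tp / (tp + fn)
                f_brute = 2 * p_ * r_ / (p_ + r_)
            den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            m_brute = (tp * tn - fp * fn) / math.sqrt(den) if den else 0.0
            assert tanimoto(c) == pytest.approx(t_brute, abs=1e-12)
            assert f1(c) == pytest.approx(f_brute, abs=1e-12)
            assert mcc(c) == pytest.approx(m_brute, abs=1e-12)
            t = tanimoto(c)
            assert f1(c) == pytest.approx(2 * t / (1 + t), abs=1e-12)


class TestGroupKfold:
    def test_groups_never_straddle_folds(self, rng):
        groups = rng.integers(0, 20, size=100)
        for tr, te in group_kfold(groups, 5, seed=1):
            assert set(groups[tr]) & set(groups[te]) == set()
            assert len(tr) + len(te) == 100

    def test_deterministic_under_seed(self):
        groups = list("aabbccddeeffgghh")
        a = [te.tolist() for _, te in group_kfold(groups, 4, seed=3)]
        b = [te.tolist() for _, te in group_kfold(groups, 4, seed=3)]
        assert a == b

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            list(group_kfold(["a", "a", "b"], 3))


class TestCrossvalMetrics:
    @staticmethod
    def _planted(seed=3, n_compounds=30, n_spectra=4):
        from ms2fp.preprocessing import preprocess_spectra
        from ms2fp.synthetic import SynthConfig, generate_compounds, generate_spectra

        cfg = SynthConfig(n_compounds=n_compounds,
                          n_spectra_per_compound=n_spectra, seed=seed)
        comps = generate_compounds(cfg)
        X, _, kept = preprocess_spectra(generate_spectra(comps, cfg))
        X = np.asarray(X.todense())
        groups = np.array([s.metadata.compound_id for s in kept])
        fpmap = {c.compound_id: c.fingerprint for c in comps}
        Y = np.vstack([fpmap[g] for g in groups]).astype(float)
        return X, Y, groups

    def test_planted_noiseless_data_scores_high(self):
        from ms2fp.evaluate import crossval_metrics
        from ms2fp.models import ModelSpec

        X, Y, groups = self._planted(n_compounds=40)
        out = crossval_metrics(
            ModelSpec("dense", X.shape[1], Y.shape[1], seed=0), X, Y,
            groups=groups, n_folds=5, seed=0,
        )
        assert out["mean"]["f1"] >= 0.9
        assert out["mean"]["tanimoto"] >= 0.9
        assert out["mean"]["mcc"] >= 0.9

    def test_shuffled_labels_give_near_zero_mcc(self, rng):
        from ms2fp.evaluate import crossval_metrics
        from ms2fp.models import ModelSpec, TrainConfig

        X, Y, groups = self._planted(seed=9)
        # break the spectrum->fingerprint link at the compound level
        uniq = list(dict.fromkeys(groups))
        perm = rng.permutation(len(uniq))
        remap = {g: uniq[perm[i]] for i, g in enumerate(uniq)}
        fp_of = {g: Y[np.flatnonzero(groups == g)[0]] for g in uniq}
        Y_shuf = np.vstack([fp_of[remap[g]] for g in groups])
        out = crossval_metrics(
            ModelSpec("dense", X.shape[1], Y.shape[1], seed=0), X, Y_shuf,
            groups=groups, n_folds=5, seed=0,
            config=TrainConfig(epochs=20, finetune_epochs=5),
        )
        assert abs(out["mean"]["mcc"]) < 0.1

    def test_deterministic_under_seed(self):
        from ms2fp.evaluate import crossval_metrics
        from ms2fp.models import ModelSpec, TrainConfig

        X, Y, groups = self._planted(seed=5, n_compounds=15, n_spectra=2)
        args = (ModelSpec("dense", X.shape[1], Y.shape[1], seed=1), X, Y)
        kwargs = dict(groups=groups, n_folds=3, seed=2,
                      config=TrainConfig(epochs=5, finetune_epochs=2))
        assert crossval_metrics(*args, **kwargs) == crossval_metrics(*args, **kwargs)


class TestHitRule:
    def test_identical_keys_hit(self):
        k = "WQZGKKKJIJFFOK-GASJEMHNSA-N"
        assert is_hit(k, k)

    def test_same_skeleton_different_suffix_hits(self):
        assert is_hit(
            "WQZGKKKJIJFFOK-GASJEMHNSA-N", "WQZGKKKJIJFFOK-DVKNGEFBSA-N"
        )

    def test_different_skeleton_misses(self):
        assert not is_hit(
            "WQZGKKKJIJFFOX-GASJEMHNSA-N", "WQZGKKKJIJFFOK-GASJEMHNSA-N"
        )

    def test_malformed_key_rejected(self):
        with pytest.raises(ValueError):
            is_hit("SHORT", "WQZGKKKJIJFFOK-GASJEMHNSA-N")


class TestStructureDisjoint:
    def _spec(self, key):
        return make_spectrum([(150.0, 10.0)], inchikey=key)

    def test_overlapping_blocks_removed(self):
        a = "A" * 14 + "-" + "B" * 10 + "-N"
        b = "C" * 14 + "-" + "B" * 10 + "-N"
        c = "D" * 14 + "-" + "B" * 10 + "-N"
        train = [self._spec(a), self._spec(b), self._spec(c)]
        retained = structure_disjoint_filter(train, [b])
        keys = {s.metadata.inchikey[:14] for s in retained}
        assert keys == {a[:14], c[:14]}

    def test_disjoint_sets_identity(self):
        a = "A" * 14 + "-" + "B" * 10 + "-N"
        train = [self._spec(a)]
        assert structure_disjoint_filter(train, ["E" * 14 + "-" + "B" * 10 + "-N"]) == train

    def test_total_overlap_empty(self):
        a = "A" * 14 + "-" + "B" * 10 + "-N"
        assert structure_disjoint_filter([self._spec(a)], [a]) == []

    def test_empty_intersection_post_filter(self, rng):
        import string

        def key():
            return (
                "".join(rng.choice(list(string.ascii_uppercase), 14))
                + "-" + "B" * 10 + "-N"
            )

        train_keys = [key() for _ in range(30)]
        test_keys = train_keys[:10] + [key() for _ in range(5)]
        retained = structure_disjoint_filter(
            [self._spec(k) for k in train_keys], test_keys
        )
        assert {s.metadata.inchikey[:14] for s in retained} & {
            k[:14] for k in test_keys
        } == set()


class TestTopK:
    def test_counting(self):
        t = topk_table([1, 2, 7], ks=(1, 3, 5, 10))
        assert t.fractions == pytest.approx([1 / 3, 2 / 3, 2 / 3, 1.0])

    def test_all_misses(self):
        t = topk_table([None, None], ks=(1, 3))
        assert t.fractions == [0.0, 0.0]

    def test_monotone_in_k_on_random_inputs(self, rng):
        for _ in range(100):
            ranks = [
                None if rng.random() < 0.2 else int(rng.integers(1, 30))
                for _ in range(20)
            ]
            fr = topk_table(ranks, ks=(1, 3, 5, 10)).fractions
            assert all(a <= b + 1e-12 for a, b in zip(fr, fr[1:]))

    def test_mode_breakdown(self):
        t = topk_table([1, 5, 2, None], ks=(1, 3), modes=["p", "p", "n", "n"])
        assert t.mode_breakdown["p"] == pytest.approx([0.5, 0.5])
        assert t.mode_breakdown["n"] == pytest.approx([0.0, 0.5])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            topk_table([])
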