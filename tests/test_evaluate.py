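"""ROC/AUC machinery and cross-validation schemes."""

import numpy as np
import pytest

from helixgram.evaluate import (
    kfold_cv,
    loocv,
    prf_at_fpr,
    roc_auc,
    vertical_average,
)
from helixgram.sequences import HelixPairSequence


def make_pairs(n, prefix="s"):
    return [HelixPairSequence(f"{prefix}{i:03d}", "GAGAG", "LILIL") for i in range(n)]


class TestRocAuc:
    @pytest.mark.parametrize(
        "pos,neg,expected",
        [
            ([2, 3], [0, 1], 1.0),
            ([1, 1], [1, 1], 0.5),
            ([3, 1], [2, 0], 0.75),  # brute force over all 4 pos x neg pairs
        ],
    )
    def test_rank_based_auc(self, pos, neg, expected):
        assert roc_auc(pos, neg).auc == pytest.approx(expected)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(1)
        curve = roc_auc(rng.normal(1, 1, 30), rng.normal(0, 1, 40))
        assert curve.fpr[0] == 0.0 and curve.fpr[-1] == 1.0
        assert curve.tpr[0] == 0.0 and curve.tpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)

    def test_complement_identity_for_tie_free_scores(self):
        rng = np.random.default_rng(2)
        pos, neg = rng.permutation(50)[:20] + 0.5, rng.permutation(50)[:20]
        assert roc_auc(pos, neg).auc + roc_auc(neg, pos).auc == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        pos, neg = rng.normal(1, 1, 25), rng.normal(0, 1, 25)
        a1 = roc_auc(pos, neg).auc
        a2 = roc_auc(np.exp(pos / 3), np.exp(neg / 3)).auc
        assert a1 == pytest.approx(a2)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            roc_auc([], [1.0])


class TestLoocv:
    def test_per_sample_auc_is_specificity_at_positive_threshold(self):
        """On random score sets the held-out AUC equals the fraction of
        negatives scoring strictly below the positive plus half the ties."""
        rng = np.random.default_rng(4)
        pos = make_pairs(6, "p")
        neg = make_pairs(10, "n")
        scores = {s.id: float(rng.integers(0, 5)) for s in pos + neg}

        def train_fn(_train):
            return lambda seqs: np.array([scores[s.id] for s in seqs])

        res = loocv(train_fn, pos, neg)
        for sid, auc in zip(res.sample_ids, res.aucs):
            s = scores[sid]
            neg_scores = np.array([scores[n.id] for n in neg])
            spec = (np.sum(neg_scores < s) + 0.5 * np.sum(neg_scores == s)) / len(neg)
            assert auc == spec

    def test_best_case_and_tie_counting(self):
        pos = make_pairs(2, "p")
        neg = make_pairs(10, "n")

        def train_fn(_train):
            def scorer(seqs):
                out = []
                for s in seqs:
                    if s.id.startswith("p"):
                        out.append(10.0)
                    else:
                        # two negatives tie with the positive, rest below
                        out.append(10.0 if s.id in ("n000", "n001") else 0.0)
                return np.array(out)

            return scorer

        res = loocv(train_fn, pos, neg)
        assert np.all(res.aucs == 0.9)  # 8 strictly below + 2 * 0.5 ties

    def test_training_failure_names_sample(self):
        pos = make_pairs(3, "p")

        def train_fn(_train):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="p000"):
            loocv(train_fn, pos, make_pairs(2, "n"))

    def test_high_specificity_subset(self):
        pos = make_pairs(4, "p")
        neg = make_pairs(4, "n")
        vals = iter([1.0, 0.5, 0.75, 0.25])
        fixed = {s.id: v for s, v in zip(pos, [1.0, 0.5, 0.75, 0.25])}

        def train_fn(_train):
            return lambda seqs: np.array(
                [10 * fixed.get(s.id, 0.0) if s.id.startswith("p") else 5.0 for s in seqs]
            )

        res = loocv(train_fn, pos, neg)
        assert set(res.high_specificity_ids) == {
            sid for sid, a in zip(res.sample_ids, res.aucs) if a >= 0.75
        }


class TestKFold:
    def test_folds_are_contiguous_blocks_by_sorted_id(self):
        pos = make_pairs(8, "p")
        seen_folds = []

        def train_fn(train_pos, seed):
            held = sorted(set(s.id for s in pos) - set(s.id for s in train_pos))
            if held not in seen_folds:
                seen_folds.append(held)
            return lambda seqs: np.arange(len(seqs), dtype=float)

        kfold_cv(train_fn, pos, make_pairs(4, "n"), k=4, combine=1)
        assert seen_folds == [
            ["p000", "p001"], ["p002", "p003"], ["p004", "p005"], ["p006", "p007"]
        ]

    def test_combine_one_combined_equals_single(self):
        rng = np.random.default_rng(6)
        pos = make_pairs(8, "p")
        neg = make_pairs(8, "n")
        table = {s.id: float(rng.normal()) for s in pos + neg}

        def train_fn(train_pos, seed):
            return lambda seqs: np.array([table[s.id] for s in seqs])

        res = kfold_cv(train_fn, pos, neg, k=4, combine=1)
        assert res.fold_combined_auc == tuple(s[0] for s in res.fold_single_aucs)
        assert res.fold_best_auc == res.fold_combined_auc


class TestVerticalAveraging:
    def test_single_curve_average_equals_itself_on_grid(self):
        rng = np.random.default_rng(7)
        curve = roc_auc(rng.normal(1, 1, 30), rng.normal(0, 1, 30))
        avg = vertical_average([curve], band=0.1)
        assert avg.mean_tpr == pytest.approx(curve.tpr_at(avg.grid))
        assert len(avg.grid) == 11

    def test_normal_approximation_halfwidth(self):
        """Averaging a perfect and a worthless curve gives mean TP rate
        0.5 in the interior, so the half-width is 1.96*sqrt(0.25/n)."""
        perfect = roc_auc([2.0, 3.0], [0.0, 1.0])
        worthless = roc_auc([0.0, 1.0], [2.0, 3.0])
        avg = vertical_average([perfect, worthless], band=0.5)
        assert avg.mean_tpr[1] == pytest.approx(0.5)
        assert avg.halfwidth[1] == pytest.approx(1.96 * np.sqrt(0.25 / 2))

    def test_mirror_curves_average_to_midpoint(self):
        # one curve with TP = FP (chance), one with TP = 1 everywhere
        chance = roc_auc(list(range(50)), list(range(50)))
        perfect = roc_auc([10.0, 11.0], [0.0, 1.0])
        avg = vertical_average([chance, perfect], band=0.25)
        expect = (chance.tpr_at(avg.grid) + perfect.tpr_at(avg.grid)) / 2
        assert avg.mean_tpr == pytest.approx(expect)

    def test_empty_curve_list_rejected(self):
        with pytest.raises(ValueError):
            vertical_average([])


class TestPrfTable:
    def test_counts_at_operating_point(self):
        curve = roc_auc([3.0, 2.0], [1.0, 0.0])  # perfect separation
        df = prf_at_fpr(curve, [0.0, 0.5])
        row0 = df.iloc[0]
        assert row0["precision"] == 1.0 and row0["recall"] == 1.0
        assert row0["f1"] == 1.0 and row0["accuracy"] == 1.0

    def test_operating_point_at_or_below_threshold(self):
        rng = np.random.default_rng(9)
        curve = roc_auc(rng.normal(1, 1, 20), rng.normal(0, 1, 20))
        df = prf_at_fpr(curve, [0.1, 0.2, 0.5])
        assert np.all(df["fpr"].values <= df["fpr_threshold"].values + 1e-12)
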