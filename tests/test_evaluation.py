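"""Segmentation metrics and Mean FA Error against brute-force oracles."""

import numpy as np
import pytest

from cordseg.evaluation import (confusion_counts, evaluate_model,
                                mean_fa_error_slice, precision_recall_dice,
                                row_normalize)
from cordseg.phantom import N_CLASSES


def brute_force_counts(pred, label):
    """Per-pixel python loop; the independent oracle for confusion_counts."""
    tp = np.zeros(N_CLASSES, dtype=int)
    fn = np.zeros(N_CLASSES, dtype=int)
    fp = np.zeros(N_CLASSES, dtype=int)
    conf = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for p, t in zip(pred.ravel(), label.ravel()):
        conf[t, p] += 1
        if p == t:
            tp[t] += 1
        else:
            fn[t] += 1
            fp[p] += 1
    return tp, fn, fp, conf


class TestConfusionCounts:
    def test_identity_masks_are_diagonal(self):
        mask = np.arange(9).reshape(3, 3)
        c = confusion_counts(mask, mask)
        assert (c["fn"] == 0).all() and (c["fp"] == 0).all()
        assert (c["confusion"] == np.eye(9, dtype=int)).all()

    def test_toy_three_by_three(self):
        label = np.ones((3, 3), dtype=int)
        pred = np.ones((3, 3), dtype=int)
        pred[0] = 2
        c = confusion_counts(pred, label)
        assert c["tp"][1] == 6 and c["fn"][1] == 3 and c["fp"][2] == 3

    def test_swapping_transposes_confusion(self):
        rng = np.random.default_rng(3)
        a, b = rng.integers(0, 9, (2, 12, 12))
        ca = confusion_counts(a, b)["confusion"]
        cb = confusion_counts(b, a)["confusion"]
        assert (ca == cb.T).all()

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            pred = rng.integers(0, 9, (16, 16))
            label = rng.integers(0, 9, (16, 16))
            c = confusion_counts(pred, label)
            tp, fn, fp, conf = brute_force_counts(pred, label)
            assert (c["tp"] == tp).all() and (c["fn"] == fn).all()
            assert (c["fp"] == fp).all() and (c["confusion"] == conf).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((2, 2), int), np.zeros((3, 3), int))


class TestPrecisionRecallDice:
    def test_hand_computed_case(self):
        counts = {"tp": np.array([6]), "fn": np.array([3]),
                  "fp": np.array([0])}
        df = precision_recall_dice(
            {k: np.pad(v, (0, 8)) for k, v in counts.items()})
        assert df.loc[0, "precision"] == pytest.approx(1.0)
        assert df.loc[0, "recall"] == pytest.approx(2 / 3, abs=5e-4)
        assert df.loc[0, "dice"] == pytest.approx(0.8)

    def test_zero_overlap_scores_zero(self):
        counts = {"tp": np.zeros(9, int), "fn": np.full(9, 2),
                  "fp": np.full(9, 2)}
        df = precision_recall_dice(counts)
        assert (df[["precision", "recall", "dice"]] == 0).all().all()

    def test_absent_class_is_nan(self):
        counts = {"tp": np.zeros(9, int), "fn": np.zeros(9, int),
                  "fp": np.zeros(9, int)}
        counts["tp"][0] = 5
        df = precision_recall_dice(counts)
        assert df.loc[0, "dice"] == 1.0
        assert df.loc[1:, "dice"].isna().all()

    def test_dice_identity_with_precision_recall(self):
        rng = np.random.default_rng(1)
        counts = {"tp": rng.integers(1, 50, 9), "fn": rng.integers(1, 50, 9),
                  "fp": rng.integers(1, 50, 9)}
        df = precision_recall_dice(counts)
        harm = 2 * df.precision * df.recall / (df.precision + df.recall)
        assert np.allclose(df.dice, harm, atol=1e-12)


class TestMeanFAError:
    def test_relative_error_hand_case(self):
        # labeled region mean 0.60, predicted region mean 0.54 -> 10%
        fa = np.array([[0.60, 0.60, 0.54, 0.54, 0.54]] )
        label = np.array([[1, 1, 0, 0, 0]])
        pred = np.array([[0, 0, 1, 1, 1]])
        df = mean_fa_error_slice(pred, label, fa)
        assert df.loc[1, "error"] == pytest.approx(0.10, abs=1e-12)

    def test_perfect_prediction_zero_error(self, sample64):
        df = mean_fa_error_slice(sample64.mask, sample64.mask, sample64.fa)
        assert (df["error"].dropna() == 0).all()

    def test_invariant_to_uniform_fa_rescaling(self, sample64):
        pred = np.roll(sample64.mask, 2, axis=1)
        d1 = mean_fa_error_slice(pred, sample64.mask, sample64.fa)
        d2 = mean_fa_error_slice(pred, sample64.mask, 0.5 * sample64.fa)
        assert np.allclose(d1["error"].dropna(), d2["error"].dropna(),
                           atol=1e-12)

    def test_empty_label_region_flagged_nan(self):
        label = np.zeros((4, 4), int)
        pred = np.zeros((4, 4), int)
        fa = np.full((4, 4), 0.2)
        df = mean_fa_error_slice(pred, label, fa)
        assert np.isnan(df.loc[3, "error"])
        assert df.loc[0, "error"] == pytest.approx(0.0)


class TestEvaluateModel:
    def test_oracle_stub_scores_perfectly(self, samples64,
                                          oracle_stub_factory):
        stub = oracle_stub_factory([s.mask for s in samples64])
        metrics, fa = evaluate_model(stub, samples64)
        assert metrics.mean_foreground_dice() == pytest.approx(1.0)
        assert fa.mean_roi_error() == pytest.approx(0.0, abs=1e-12)
        diag = np.diag(metrics.confusion)
        assert np.allclose(diag, 1.0)

    def test_background_only_predictor_has_zero_recall(self, samples64,
                                                       oracle_stub_factory):
        stub = oracle_stub_factory(
            [np.zeros_like(s.mask) for s in samples64])
        metrics, _ = evaluate_model(stub, samples64)
        roi_rows = metrics.summary.iloc[1:9]
        assert (roi_rows["recall_mean"] == 0).all()

    def test_confusion_rows_sum_to_one(self, samples64, oracle_stub_factory):
        stub = oracle_stub_factory(
            [np.roll(s.mask, 1, axis=0) for s in samples64])
        metrics, _ = evaluate_model(stub, samples64)
        assert np.allclose(metrics.confusion.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_dataset_rejected(self, oracle_stub_factory):
        with pytest.raises(ValueError):
            evaluate_model(oracle_stub_factory([]), [])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        pred = rng.integers(0, 9, (20, 20))
        label = rng.integers(0, 9, (20, 20))
        perm = rng.permutation(9)
        c1 = confusion_counts(pred, label)
        c2 = confusion_counts(perm[pred], perm[label])
        assert (c2["tp"][perm] == c1["tp"]).all()
        # conf2[perm[t], perm[p]] == conf1[t, p]
        for t in range(9):
            for p in range(9):
                assert c2["confusion"][perm[t], perm[p]] \
                    == c1["confusion"][t, p]

    def test_row_normalize_empty_row_nan(self):
        conf = np.zeros((9, 9), int)
        conf[0, 0] = 4
        norm = row_normalize(conf)
        assert norm[0, 0] == 1.0
        assert np.isnan(norm[1]).all()
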