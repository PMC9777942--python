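import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gliocascade.errors import ConfigError, DataError, ShapeError
from gliocascade.metrics import (ConfusionCounts, FoldReport, MetricsRecord,
                                 accuracy, aggregate_percent, confusion, dice,
                                 kfold_evaluate, make_split, round_percent,
                                 sensitivity, split_counts)
from gliocascade import reference


def brute_force_confusion(pred, truth):
    """Oracle: explicit triple-loop tally over the voxel grid."""
    tp = fp = tn = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            for k in range(pred.shape[2]):
                p, t = bool(pred[i, j, k]), bool(truth[i, j, k])
                if p and t:
                    tp += 1
                elif p and not t:
                    fp += 1
                elif not p and t:
                    fn += 1
                else:
                    tn += 1
    return tp, fp, tn, fn


class TestConfusion:
    def test_perfect_prediction(self):
        truth = np.zeros((10, 10, 1), dtype=np.uint8)
        truth.ravel()[:10] = 1
        c = confusion(truth, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 90, 0, 0)

    def test_complement_prediction(self):
        truth = (np.arange(27).reshape(3, 3, 3) % 2).astype(np.uint8)
        c = confusion(1 - truth, truth)
        assert c.tp == 0 and c.tn == 0
        assert c.total == 27

    def test_matches_brute_force_tally(self, rng):
        for _ in range(10):
            pred = rng.integers(0, 2, size=(4, 4, 4))
            truth = rng.integers(0, 2, size=(4, 4, 4))
            c = confusion(pred, truth)
            assert (c.tp, c.fp, c.tn, c.fn) == tuple(
                brute_force_confusion(pred, truth)[i] for i in (0, 1, 2, 3))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            confusion(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))


class TestMetricFormulas:
    def test_dice_frozen_example(self):
        assert dice(ConfusionCounts(tp=2, fp=1, tn=0, fn=1)) == pytest.approx(4 / 6)

    def test_dice_conventions(self):
        assert dice(ConfusionCounts(tp=5, fp=0, tn=5, fn=0)) == 1.0
        assert dice(ConfusionCounts(tp=0, fp=3, tn=0, fn=3)) == 0.0
        assert dice(ConfusionCounts(tp=0, fp=0, tn=9, fn=0)) == 1.0  # both empty

    def test_sensitivity(self):
        assert sensitivity(ConfusionCounts(tp=8, fp=0, tn=0, fn=2)) == pytest.approx(0.8)
        assert sensitivity(ConfusionCounts(tp=3, fp=1, tn=1, fn=0)) == 1.0
        assert np.isnan(sensitivity(ConfusionCounts(tp=0, fp=2, tn=5, fn=0)))

    def test_accuracy(self):
        assert accuracy(ConfusionCounts(tp=2, tn=6, fp=1, fn=1)) == pytest.approx(0.8)
        with pytest.raises(DataError):
            accuracy(ConfusionCounts(tp=0, fp=0, tn=0, fn=0))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_dice_symmetric_accuracy_flip_invariant(self, tp, fp, tn, fn):
        c = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
        swapped = ConfusionCounts(tp=tp, fp=fn, tn=tn, fn=fp)  # pred<->truth
        assert dice(c) == pytest.approx(dice(swapped))
        if c.total > 0:
            flipped = ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp)  # flip both
            assert accuracy(c) == pytest.approx(accuracy(flipped))


class TestSplit:
    def test_reference_image_counts(self):
        assert split_counts(reference.HGG_N_IMAGES) == reference.HGG_SPLIT_COUNTS

    def test_small_n_floor_arithmetic(self):
        assert split_counts(20) == (14, 3, 3)
        assert split_counts(0) == (0, 0, 0)

    def test_split_partitions_ids(self):
        plan = make_split(range(100), seed=4)
        assert sorted(plan.ids("train") + plan.ids("val") + plan.ids("test")) == \
            list(range(100))
        assert plan.counts == (70, 15, 15)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigError):
            make_split(range(10), fractions=(0.5, 0.6, -0.1))


class TestAggregation:
    def test_rounding_is_half_up(self):
        assert round_percent(88.75) == 88.8
        assert round_percent(88.74999999999999) == 88.8
        assert round_percent(84.725) == 84.7
        assert round_percent(83.173) == 83.2

    def test_reference_fold_columns_reproduce_printed_averages(self):
        t = reference.TENFOLD_HGG
        assert aggregate_percent(t["dice"]) == reference.TENFOLD_AVG["hgg"]["dice"]
        assert aggregate_percent(t["sensitivity"]) == \
            reference.TENFOLD_AVG["hgg"]["sensitivity"]
        assert aggregate_percent(t["accuracy"]) == \
            reference.TENFOLD_AVG["hgg"]["accuracy"]

    def test_constant_folds_aggregate_to_constant(self):
        report = FoldReport.from_percent_columns([50.0] * 10, [50.0] * 10, [50.0] * 10)
        assert report.aggregate.dice == 50.0
        frame = report.to_frame()
        assert len(frame) == 11 and frame.iloc[-1]["fold"] == "Avg. (%)"


class TestKFold:
    def test_folds_partition_cases(self):
        cases = list(range(10))
        seen = []

        def train_fn(train_cases):
            return None

        def eval_fn(model, test_cases):
            seen.extend(test_cases)
            return MetricsRecord(dice=0.5, sensitivity=0.5, accuracy=0.5)

        report = kfold_evaluate(cases, train_fn, eval_fn, k=10, seed=0)
        assert sorted(seen) == cases  # each case in exactly one test fold
        assert len(report.per_fold) == 10
        assert report.aggregate.dice == 50.0

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ConfigError):
            kfold_evaluate([1, 2, 3], lambda c: None, lambda m, c: None, k=10)
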