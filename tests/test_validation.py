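import numpy as np
import pytest

from breathomix import (
    PipelineConfig,
    PredictionRecord,
    bootstrap_ci,
    classify,
    confusion_metrics,
    double_cross_validate,
    roc_curve,
    stratified_folds,
)
from breathomix.core import Measurement

from oracles import oracle_auc_pairs


def make_records(values, truth_pos, positive="pos", negative="neg"):
    return [
        PredictionRecord(
            patient_id=f"p{i}",
            true_label=positive if t else negative,
            value=float(v),
            outer_fold=0,
            predicted_label=positive if v >= 0 else negative,
        )
        for i, (v, t) in enumerate(zip(values, truth_pos))
    ]


class TestClassify:
    def test_positive_above_threshold(self):
        assert classify(0.3, 0.0, "colon", "HNSCC") == "colon"

    def test_negative_below_threshold(self):
        assert classify(-0.2, 0.0, "colon", "HNSCC") == "HNSCC"

    def test_boundary_value_is_positive(self):
        assert classify(0.0, 0.0, "colon", "HNSCC") == "colon"


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        recs = make_records([0.8, 0.9, -0.7, -0.6], [True, True, False, False])
        s = confusion_metrics(recs, "pos")
        assert (s.sensitivity, s.specificity, s.accuracy, s.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_study_scale_confusion_table(self):
        # TP=22, FN=6, TN=81, FP=19 (the 28-vs-100 comparison at its rounded
        # 79%/81%/81% operating point)
        values = [0.5] * 22 + [-0.5] * 6 + [-0.5] * 81 + [0.5] * 19
        truth = [True] * 28 + [False] * 100
        s = confusion_metrics(make_records(values, truth), "pos")
        assert (s.tp, s.fn, s.tn, s.fp) == (22, 6, 81, 19)
        assert s.sensitivity == pytest.approx(22 / 28)
        assert s.specificity == pytest.approx(0.81)
        assert s.accuracy == pytest.approx(103 / 128)
        expected_mcc = (22 * 81 - 19 * 6) / np.sqrt(41 * 28 * 100 * 87)
        assert s.mcc == pytest.approx(expected_mcc)
        assert s.mcc == pytest.approx(0.528, abs=5e-4)

    def test_all_positive_predictions_mcc_zero_by_convention(self):
        recs = make_records([0.5, 0.6, 0.7, 0.8], [True, True, False, False])
        assert confusion_metrics(recs, "pos").mcc == 0.0

    def test_counts_reconstructable_from_records(self, rng):
        values = rng.uniform(-1, 1, 60)
        truth = rng.random(60) < 0.4
        if not truth.any() or truth.all():
            truth[0], truth[1] = True, False
        recs = make_records(values, truth)
        s = confusion_metrics(recs, "pos")
        tp = sum(1 for r in recs if r.predicted_label == "pos" and r.true_label == "pos")
        assert s.tp == tp and s.tp + s.fp + s.tn + s.fn == 60

    def test_single_class_rejected(self):
        recs = make_records([0.1, 0.2], [True, True])
        with pytest.raises(ValueError, match="both classes"):
            confusion_metrics(recs, "pos")

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import matthews_corrcoef

        for _ in range(20):
            values = rng.uniform(-1, 1, 40)
            truth = rng.random(40) < 0.5
            if truth.all() or not truth.any():
                continue
            recs = make_records(values, truth)
            s = confusion_metrics(recs, "pos")
            sk = matthews_corrcoef(truth, values >= 0)
            assert s.mcc == pytest.approx(sk, abs=1e-12)


class TestROC:
    def test_perfect_separation_auc_one(self):
        recs = make_records([0.9, 0.8, -0.8, -0.9], [True, True, False, False])
        assert roc_curve(recs, "pos").auc == pytest.approx(1.0)

    def test_constant_values_auc_half(self):
        recs = make_records([0.2] * 6, [True, True, False, False, False, True])
        assert roc_curve(recs, "pos").auc == pytest.approx(0.5)

    def test_auc_equals_pair_counting_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(8, 40))
            values = np.round(rng.uniform(-1, 1, n), 1)  # force ties
            truth = rng.random(n) < 0.5
            if truth.all() or not truth.any():
                continue
            recs = make_records(values, truth)
            auc = roc_curve(recs, "pos").auc
            oracle = oracle_auc_pairs(values[truth], values[~truth])
            assert auc == pytest.approx(oracle, abs=1e-12)

    def test_monotone_curve(self, rng):
        values = rng.uniform(-1, 1, 50)
        truth = rng.random(50) < 0.4
        truth[0], truth[1] = True, False
        roc = roc_curve(make_records(values, truth), "pos")
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)
        assert roc.fpr[0] == 0 and roc.tpr[-1] == 1

    def test_auc_invariant_under_increasing_transform(self, rng):
        values = rng.uniform(-1, 1, 40)
        truth = rng.random(40) < 0.5
        truth[0], truth[1] = True, False
        a1 = roc_curve(make_records(values, truth), "pos").auc
        a2 = roc_curve(make_records(np.tanh(3 * values) ** 3, truth), "pos").auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            values = rng.uniform(-1, 1, 50)
            truth = rng.random(50) < 0.5
            if truth.all() or not truth.any():
                continue
            auc = roc_curve(make_records(values, truth), "pos").auc
            assert auc == pytest.approx(roc_auc_score(truth, values), abs=1e-12)


class TestBootstrap:
    def test_constant_metric_degenerate_interval(self):
        recs = make_records([0.5] * 10 + [-0.5] * 10, [True] * 10 + [False] * 10)
        lo, hi = bootstrap_ci(recs, "accuracy", "pos", B=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_mcc_interval_within_range(self, rng):
        values = rng.uniform(-1, 1, 40)
        truth = rng.random(40) < 0.5
        truth[0], truth[1] = True, False
        lo, hi = bootstrap_ci(make_records(values, truth), "mcc", "pos", B=200, seed=1)
        assert -1.0 <= lo <= hi <= 1.0

    def test_deterministic_given_seed(self, rng):
        values = rng.uniform(-1, 1, 30)
        truth = rng.random(30) < 0.5
        truth[0], truth[1] = True, False
        recs = make_records(values, truth)
        assert bootstrap_ci(recs, "auc", "pos", B=150, seed=5) == \
            bootstrap_ci(recs, "auc", "pos", B=150, seed=5)

    def test_small_B_rejected(self):
        recs = make_records([0.5, -0.5], [True, False])
        with pytest.raises(ValueError, match="B"):
            bootstrap_ci(recs, "accuracy", "pos", B=10, seed=0)


class TestStratifiedFolds:
    def test_partition(self):
        labels = ["a"] * 13 + ["b"] * 7
        folds = stratified_folds(labels, 4, seed=0)
        allidx = np.sort(np.concatenate(folds))
        assert np.array_equal(allidx, np.arange(20))

    def test_class_absent_from_training_fold_rejected(self):
        # two b's across two folds: every training fold keeps one b
        stratified_folds(["a"] * 10 + ["b", "b"], 2, seed=0)
        with pytest.raises(ValueError, match="smaller k"):
            # a single b is always absent from its own training fold
            stratified_folds(["a"] * 10 + ["b"], 2, seed=0)


class TestDoubleCV:
    def test_one_record_per_patient_and_bounded_values(self, small_cohort):
        meas, _ = small_cohort
        cfg = PipelineConfig(
            scaling_names=("log_baseline_ratio",), hidden_sizes=(4,),
            n_weight_seeds=1, epochs=300, allow_reuse=True,
        )
        res = double_cross_validate(meas, cfg, outer_k=3, inner_k=2, seed=1)
        assert sorted(r.patient_id for r in res.records) == sorted(m.patient_id for m in meas)
        assert all(-1 <= r.value <= 1 for r in res.records)
        assert res.positive_class == "colon"  # smaller class is positive
        fold_sizes = [len(a.test_ids) for a in res.folds]
        assert sum(fold_sizes) == len(meas)

    def test_duplicate_patient_ids_rejected(self, small_cohort):
        meas, _ = small_cohort
        dup = [meas[0]] + list(meas)
        with pytest.raises(ValueError, match="duplicate"):
            double_cross_validate(dup, PipelineConfig(), outer_k=3, inner_k=2, seed=0)

    def test_more_than_two_classes_rejected(self, small_cohort):
        meas, _ = small_cohort
        extra = Measurement("px", "bladder", 259, np.ones((64, 36, 3)))
        with pytest.raises(ValueError, match="exactly 2"):
            double_cross_validate(list(meas) + [extra], PipelineConfig(), seed=0)
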