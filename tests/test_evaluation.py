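import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from _oracles import brute_force_auc, permutation_ks_pvalue, trapezoidal_roc_auc
from hergsift.classifier import (
    BINDER_CLASS,
    NONBINDER_CLASS,
    ScoreStandardizer,
    TrainedClassifier,
    build_features,
)
from hergsift.evaluation import (
    ConfusionCounts,
    MetricDistribution,
    ResamplingProtocol,
    ThresholdScanConfig,
    compare_models,
    compute_auc,
    compute_metrics,
    confusion_counts,
    ds_threshold,
    ks_two_sample,
    resample_evaluate,
)
from hergsift.synthetic_data import SyntheticSpec, make_dataset


class TestComputeMetrics:
    def test_perfect_classifier(self):
        ms = compute_metrics(ConfusionCounts(TP=50, FN=0, TN=50, FP=0))
        assert (ms.ACC, ms.SE, ms.SP, ms.NPV) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_arithmetic(self):
        ms = compute_metrics(ConfusionCounts(TP=40, FN=10, TN=35, FP=15))
        assert ms.ACC == 0.75
        assert ms.SE == 0.80
        assert ms.SP == 0.70
        assert ms.NPV == pytest.approx(35 / 45)

    def test_empty_predicted_negative_set_gives_nan_npv(self):
        ms = compute_metrics(ConfusionCounts(TP=10, FN=0, TN=0, FP=5))
        assert math.isnan(ms.NPV) and not math.isnan(ms.ACC)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, FN=0, TN=0, FP=0)

    def test_balanced_accuracy_identity(self, rng):
        # on balanced external sets ACC = (SE + SP) / 2
        for _ in range(50):
            n = 50
            tp = int(rng.integers(0, n + 1))
            tn = int(rng.integers(0, n + 1))
            ms = compute_metrics(ConfusionCounts(TP=tp, FN=n - tp,
                                                 TN=tn, FP=n - tn))
            assert ms.ACC == pytest.approx((ms.SE + ms.SP) / 2, abs=1e-12)


class TestComputeAuc:
    def test_perfect_separation(self):
        assert compute_auc([3, 2, 1, 0], [1, 1, -1, -1]) == 1.0

    def test_all_ties_give_half(self):
        assert compute_auc([1, 1, 1, 1], [1, 1, -1, -1]) == 0.5

    def test_one_swap_gives_three_quarters(self):
        assert compute_auc([3, 1, 2, 0], [1, 1, -1, -1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([1, 2], [1, 1])

    def test_matches_brute_force_and_trapezoid_and_sklearn(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 20))
            scores = rng.integers(0, 6, n).astype(float)  # force ties
            labels = rng.choice([1, -1], n)
            if len(set(labels)) < 2:
                continue
            got = compute_auc(scores, labels)
            assert got == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)
            assert got == pytest.approx(
                trapezoidal_roc_auc(list(scores), list(labels)), abs=1e-12)
            assert got == pytest.approx(
                roc_auc_score((labels + 1) // 2, scores), abs=1e-12)


class TestKSTwoSample:
    def test_identical_samples(self):
        stat, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        stat, _ = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert stat == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_exact_p_matches_permutation_enumeration(self, rng):
        # tie-free small samples; oracle enumerates every pooled split
        for _ in range(15):
            n_a = int(rng.integers(2, 5))
            n_b = int(rng.integers(2, 5))
            pooled = rng.permutation(rng.normal(size=n_a + n_b))
            a, b = list(pooled[:n_a]), list(pooled[n_a:])
            stat, p = ks_two_sample(a, b)
            assert p == pytest.approx(permutation_ks_pvalue(a, b), abs=1e-9)

    def test_spec_worked_example(self):
        a, b = [1.0, 2.0], [1.5, 3.0]
        stat, p = ks_two_sample(a, b)
        assert stat == 0.5
        assert p == pytest.approx(permutation_ks_pvalue(a, b), abs=1e-9)


class TestCompareModels:
    @staticmethod
    def dist(values):
        df = pd.DataFrame({"ACC": values})
        return MetricDistribution(df)

    def test_distribution_vs_itself(self):
        d = self.dist(np.linspace(0.6, 0.8, 100))
        assert compare_models(d, d, "ACC") == 1.0

    def test_large_shift_is_detected(self, rng):
        d1 = self.dist(rng.normal(0.70, 0.01, 100))
        d2 = self.dist(rng.normal(0.80, 0.01, 100))
        assert compare_models(d1, d2, "ACC") < 1e-10

    def test_missing_metric_is_error(self):
        d = self.dist([0.5] * 10)
        with pytest.raises(KeyError):
            compare_models(d, d, "MCC")


def linear_ds_model(weight, bias, mu=-6.0, sigma=1.0):
    return TrainedClassifier(
        weights=np.array([weight]), bias=bias, lambda_=0.1,
        standardizer=ScoreStandardizer(mu, sigma), feature_names=("ds_st",))


class TestDsThreshold:
    def test_analytic_crossing_at_mu(self):
        model = linear_ds_model(1.0, 0.0)
        thr = ds_threshold(model, ThresholdScanConfig(range=(-8.0, -4.0)))
        assert abs(thr - (-6.0)) <= 0.005 + 1e-9

    def test_bias_shifts_crossing(self):
        model = linear_ds_model(1.0, -0.5)
        thr = ds_threshold(model, ThresholdScanConfig(range=(-8.0, -4.0)))
        assert abs(thr - (-5.5)) <= 0.01 + 1e-9

    def test_random_models_within_one_step_of_analytic(self, rng):
        for _ in range(100):
            w = float(rng.uniform(0.2, 3.0)) * float(rng.choice([-1, 1]))
            b = float(rng.uniform(-1.0, 1.0))
            mu = float(rng.uniform(-9.0, -5.0))
            sigma = float(rng.uniform(0.5, 2.0))
            analytic = mu - sigma * b / w
            model = linear_ds_model(w, b, mu, sigma)
            cfg = ThresholdScanConfig(range=(analytic - 2.0, analytic + 2.0))
            thr = ds_threshold(model, cfg)
            assert abs(thr - analytic) <= cfg.step + 1e-9

    def test_no_flip_returns_nan(self):
        model = linear_ds_model(1.0, 10.0)
        thr = ds_threshold(model, ThresholdScanConfig(range=(-8.0, -4.0)))
        assert math.isnan(thr)

    def test_multifeature_model_rejected(self):
        model = TrainedClassifier(
            weights=np.array([1.0, 1.0]), bias=0.0, lambda_=0.1,
            standardizer=ScoreStandardizer(-6, 1),
            feature_names=("ds_st", "bit"))
        with pytest.raises(ValueError):
            ds_threshold(model, ThresholdScanConfig(range=(-8, -4)))


def synthetic_features(seed=0, n=150, delta=2.0):
    data = make_dataset(SyntheticSpec(
        n_binders=n, n_nonbinders=n,
        ds_mean_binder=-6.0 - delta, ds_mean_nonbinder=-6.0, seed=seed))
    std = ScoreStandardizer.fit(data.ds)
    X = build_features(pd.Series(std.transform(data.ds), index=data.ds.index))
    return X, data.labels


class TestResampleEvaluate:
    def test_distribution_length_equals_repeats(self):
        X, y = synthetic_features()
        dist = resample_evaluate(X, y, ResamplingProtocol(n_repeats=5, seed=0))
        assert len(dist.per_repeat) == 5

    def test_deterministic_under_seed(self):
        X, y = synthetic_features()
        p = ResamplingProtocol(n_repeats=4, seed=7)
        d1 = resample_evaluate(X, y, p)
        d2 = resample_evaluate(X, y, p)
        pd.testing.assert_frame_equal(d1.per_repeat, d2.per_repeat)

    def test_perfectly_separable_feature_gives_acc_one(self):
        X, y = synthetic_features(delta=30.0)
        dist = resample_evaluate(X, y, ResamplingProtocol(n_repeats=5, seed=1))
        assert dist.mean("ACC") == 1.0 and dist.sd("ACC") == 0.0

    def test_insufficient_class_counts_rejected(self):
        X, y = synthetic_features(n=60)
        with pytest.raises(ValueError, match="need >="):
            resample_evaluate(
                X, y, ResamplingProtocol(external_n_per_class=55, seed=0))

    def test_balanced_external_set_satisfies_acc_identity(self):
        X, y = synthetic_features()
        dist = resample_evaluate(X, y, ResamplingProtocol(n_repeats=5, seed=2))
        np.testing.assert_allclose(
            dist.metric("ACC"),
            (dist.metric("SE") + dist.metric("SP")) / 2, atol=1e-12)
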