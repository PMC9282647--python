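"""Balanced-resampling model evaluation and docking-score thresholds.

The external-validation protocol: in each of ``n_repeats`` (default 100)
repeats, 50 binders and 50 nonbinders are drawn without replacement as an
external set unseen by the classifier; a class-balanced training set is
drawn from the remainder (majority class undersampled); the model is trained
and scored on the external compounds. The resulting per-repeat metric values
form a distribution whose mean +/- sd summarises the model and whose shape
feeds two-sample Kolmogorov-Smirnov comparisons between models.

Metrics: ACC = (TP+TN)/(TP+TN+FP+FN), SE = TP/(TP+FN), SP = TN/(TN+FP),
NPV = TN/(TN+FN); AUC is the Mann-Whitney probability that a binder
outscores a nonbinder (ties counted half).

``ds_threshold`` recovers, for a docking-score-only linear classifier, the
raw score at which the predicted label flips from active to inactive by
scanning the observed score range at a fixed step (default 0.01).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import (
    BINDER_CLASS,
    NONBINDER_CLASS,
    RegularizationConfig,
    TrainedClassifier,
    predict,
    train_l1_svm,
)

logger = logging.getLogger(__name__)

METRIC_NAMES = ("ACC", "SE", "SP", "NPV", "AUC")


@dataclass(frozen=True)
class ResamplingProtocol:
    n_repeats: int = 100
    external_n_per_class: int = 50
    balanced_training: bool = True
    with_auc: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")
        if self.external_n_per_class < 1:
            raise ValueError("external_n_per_class must be >= 1")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricSet:
    ACC: float
    SE: float
    SP: float
    NPV: float
    AUC: float = math.nan


@dataclass(frozen=True)
class MetricDistribution:
    """Per-repeat metric values with mean +/- sd summaries."""

    per_repeat: pd.DataFrame  # one row per repeat, columns METRIC_NAMES

    def metric(self, name: str) -> np.ndarray:
        if name not in self.per_repeat.columns:
            raise KeyError(f"metric {name!r} not recorded")
        return self.per_repeat[name].to_numpy()

    def mean(self, name: str) -> float:
        return float(np.nanmean(self.metric(name)))

    def sd(self, name: str) -> float:
        return float(np.nanstd(self.metric(name), ddof=1))

    def summary(self, decimals: int = 2) -> pd.DataFrame:
        rows = {
            m: {"mean": round(self.mean(m), decimals),
                "sd": round(self.sd(m), decimals)}
            for m in self.per_repeat.columns
            if not np.all(np.isnan(self.metric(m)))
        }
        return pd.DataFrame(rows).T


@dataclass(frozen=True)
class ThresholdScanConfig:
    step: float = 0.01
    range: tuple[float, float] | None = None  # default: observed DS range

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")


# ---------------------------------------------------------------------------
# Elementary metrics
# ---------------------------------------------------------------------------

def compute_metrics(cc: ConfusionCounts) -> MetricSet:
    """Exact formula evaluation; an empty denominator yields NaN (reported as
    not-available) rather than halting the run."""

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    total = cc.TP + cc.TN + cc.FP + cc.FN
    return MetricSet(
        ACC=ratio(cc.TP + cc.TN, total),
        SE=ratio(cc.TP, cc.TP + cc.FN),
        SP=ratio(cc.TN, cc.TN + cc.FP),
        NPV=ratio(cc.TN, cc.TN + cc.FN),
    )


def confusion_counts(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    t = np.asarray(y_true, int)
    p = np.asarray(y_pred, int)
    return ConfusionCounts(
        TP=int(np.sum((t == BINDER_CLASS) & (p == BINDER_CLASS))),
        FN=int(np.sum((t == BINDER_CLASS) & (p == NONBINDER_CLASS))),
        TN=int(np.sum((t == NONBINDER_CLASS) & (p == NONBINDER_CLASS))),
        FP=int(np.sum((t == NONBINDER_CLASS) & (p == BINDER_CLASS))),
    )


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(score_binder > score_nonbinder) + 0.5 P(tie),
    computed from midranks so ties are counted half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = y == BINDER_CLASS
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("compute_auc requires both classes")
    ranks = stats.rankdata(s)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample KS test; exact p for min(n) <= 25, else asymptotic."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_two_sample requires non-empty samples")
    method = "exact" if min(a.size, b.size) <= 25 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def compare_models(
    dist1: MetricDistribution, dist2: MetricDistribution, metric: str
) -> float:
    """KS p-value comparing the two models' per-repeat metric distributions."""
    m1, m2 = dist1.metric(metric), dist2.metric(metric)
    if len(m1) != len(m2):
        raise ValueError("metric lists differ in length")
    return ks_two_sample(m1, m2)[1]


# ---------------------------------------------------------------------------
# Resampling protocol
# ---------------------------------------------------------------------------

Trainer = Callable[[pd.DataFrame, np.ndarray, int], TrainedClassifier]


def default_trainer(
    X: pd.DataFrame, y: np.ndarray, seed: int,
    cfg: RegularizationConfig = RegularizationConfig(),
) -> TrainedClassifier:
    return train_l1_svm(X, y, cfg, seed=seed)


def resample_evaluate(
    features: pd.DataFrame,
    labels: pd.Series,
    protocol: ResamplingProtocol = ResamplingProtocol(),
    trainer: Trainer = default_trainer,
) -> MetricDistribution:
    """Run the balanced resampling protocol and collect metric distributions.

    ``features`` rows and ``labels`` are aligned on compound_id; labels are
    +1 (binder) / -1 (nonbinder). External compounds of a repeat never enter
    that repeat's training set.
    """
    labels = labels.reindex(features.index)
    if labels.isna().any():
        raise ValueError("labels missing for some feature rows")
    y = labels.to_numpy(int)
    pos_idx = np.flatnonzero(y == BINDER_CLASS)
    neg_idx = np.flatnonzero(y == NONBINDER_CLASS)
    need = protocol.external_n_per_class + 10
    if len(pos_idx) < need or len(neg_idx) < need:
        raise ValueError(
            f"need >= {need} compounds per class "
            f"(have {len(pos_idx)} binders, {len(neg_idx)} nonbinders)"
        )

    rows = []
    for rep in range(protocol.n_repeats):
        rng = np.random.default_rng([protocol.seed, rep])
        ext_pos = rng.choice(pos_idx, protocol.external_n_per_class, replace=False)
        ext_neg = rng.choice(neg_idx, protocol.external_n_per_class, replace=False)
        ext = np.concatenate([ext_pos, ext_neg])
        rem_pos = np.setdiff1d(pos_idx, ext_pos)
        rem_neg = np.setdiff1d(neg_idx, ext_neg)
        if protocol.balanced_training:
            n_train = min(len(rem_pos), len(rem_neg))
            rem_pos = rng.choice(rem_pos, n_train, replace=False)
            rem_neg = rng.choice(rem_neg, n_train, replace=False)
        train = np.concatenate([rem_pos, rem_neg])

        rep_seed = int(rng.integers(2**31 - 1))
        model = trainer(features.iloc[train], y[train], rep_seed)
        pred, margins = predict(model, features.iloc[ext])
        ms = compute_metrics(confusion_counts(y[ext], pred))
        auc = compute_auc(margins, y[ext]) if protocol.with_auc else math.nan
        rows.append({"ACC": ms.ACC, "SE": ms.SE, "SP": ms.SP,
                     "NPV": ms.NPV, "AUC": auc})
    return MetricDistribution(pd.DataFrame(rows, columns=list(METRIC_NAMES)))


# ---------------------------------------------------------------------------
# Docking-score decision threshold
# ---------------------------------------------------------------------------

def ds_threshold(
    model: TrainedClassifier,
    cfg: ThresholdScanConfig = ThresholdScanConfig(),
    observed_ds: Sequence[float] | None = None,
) -> float:
    """Scan raw docking scores across the observed range at ``cfg.step`` and
    return the score where the predicted label flips (raw score units).

    The scan range defaults to the observed raw-score range; for a linear
    one-feature model the flip is unique. Returns NaN (with a warning) when
    no flip occurs inside the range.
    """
    if not model.is_ds_only:
        raise ValueError("ds_threshold applies to docking-score-only models")
    if model.standardizer is None:
        raise ValueError("model lacks a score standardizer")
    if cfg.range is not None:
        lo, hi = cfg.range
    elif observed_ds is not None:
        lo, hi = float(np.min(observed_ds)), float(np.max(observed_ds))
    else:
        raise ValueError("provide cfg.range or observed_ds")
    grid = np.arange(lo, hi + cfg.step / 2, cfg.step)
    margins = model.standardizer.transform(grid) * model.weights[0] + model.bias
    pred = margins > 0
    flips = np.flatnonzero(pred[1:] != pred[:-1])
    if flips.size == 0:
        logger.warning("no label flip in DS range [%.3f, %.3f]", lo, hi)
        return math.nan
    i = flips[0]
    return float((grid[i] + grid[i + 1]) / 2.0)


def threshold_distribution(
    features: pd.DataFrame,
    labels: pd.Series,
    raw_ds: pd.Series,
    protocol: ResamplingProtocol = ResamplingProtocol(),
    trainer: Trainer | None = None,
    scan: ThresholdScanConfig = ThresholdScanConfig(),
) -> tuple[float, float, list[float]]:
    """Per-repeat DS thresholds of a DS-only model: (mean, sd, values)."""
    from .classifier import ScoreStandardizer

    labels = labels.reindex(features.index)
    raw_ds = raw_ds.reindex(features.index)
    y = labels.to_numpy(int)
    pos_idx = np.flatnonzero(y == BINDER_CLASS)
    neg_idx = np.flatnonzero(y == NONBINDER_CLASS)
    values: list[float] = []
    for rep in range(protocol.n_repeats):
        rng = np.random.default_rng([protocol.seed, rep])
        ext_pos = rng.choice(pos_idx, protocol.external_n_per_class, replace=False)
        ext_neg = rng.choice(neg_idx, protocol.external_n_per_class, replace=False)
        rem_pos = np.setdiff1d(pos_idx, ext_pos)
        rem_neg = np.setdiff1d(neg_idx, ext_neg)
        if protocol.balanced_training:
            n_train = min(len(rem_pos), len(rem_neg))
            rem_pos = rng.choice(rem_pos, n_train, replace=False)
            rem_neg = rng.choice(rem_neg, n_train, replace=False)
        train = np.concatenate([rem_pos, rem_neg])
        std = ScoreStandardizer.fit(raw_ds.iloc[train])
        X = pd.DataFrame({"ds_st": std.transform(raw_ds.iloc[train])},
                         index=features.index[train])
        rep_seed = int(rng.integers(2**31 - 1))
        if trainer is None:
            model = train_l1_svm(X, y[train], seed=rep_seed, standardizer=std)
        else:
            model = trainer(X, y[train], rep_seed)
        thr = ds_threshold(model, scan, observed_ds=raw_ds.iloc[train])
        if not math.isnan(thr):
            values.append(thr)
    if not values:
        return math.nan, math.nan, values
    return float(np.mean(values)), float(np.std(values, ddof=1)), values
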