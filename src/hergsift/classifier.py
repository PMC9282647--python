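"""L1-regularized linear SVM on docking scores and interaction fingerprints.

Feature construction follows the fused-vector convention: the docking score
is standardized to DSst = (DS - mu) / sigma with mu and sigma taken from the
training scores, and each fingerprint bit is mapped from {0, 1} to {-1, +1}
so continuous and binary predictors share one vector. The classifier is a
linear SVM with an L1 penalty (LASSO constraint) whose regularization
strength lambda, on a grid inside (0, 1), is selected by minimum
classification error on a held-out tuning split; the L1 penalty drives the
weights of uninformative fingerprint bits to exactly zero.

Class encoding: binder = +1, nonbinder = -1; decision = sign(w.x + b).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.svm import LinearSVC

BINDER_CLASS = 1
NONBINDER_CLASS = -1

DEFAULT_LAMBDA_GRID = tuple(np.geomspace(1e-3, 0.99, 20))


@dataclass(frozen=True)
class ScoreStandardizer:
    """(DS - mu) / sigma transform with moments from the training scores."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0 (constant training scores?)")

    @classmethod
    def fit(cls, ds: Sequence[float]) -> "ScoreStandardizer":
        arr = np.asarray(ds, float)
        sigma = float(arr.std(ddof=1))
        if not sigma > 0:
            raise ValueError("cannot standardize constant docking scores")
        return cls(mu=float(arr.mean()), sigma=sigma)

    def transform(self, ds) -> np.ndarray:
        return (np.asarray(ds, float) - self.mu) / self.sigma

    def inverse(self, ds_st) -> np.ndarray:
        return np.asarray(ds_st, float) * self.sigma + self.mu


@dataclass(frozen=True)
class RegularizationConfig:
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    tuning_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not self.lambda_grid:
            raise ValueError("lambda grid is empty")
        if any(not (0 < lam < 1) for lam in self.lambda_grid):
            raise ValueError("every lambda must lie in (0, 1)")
        if not (0 < self.tuning_fraction < 1):
            raise ValueError("tuning_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class TrainedClassifier:
    weights: np.ndarray
    bias: float
    lambda_: float
    standardizer: ScoreStandardizer | None
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.feature_names):
            raise ValueError("weights and feature_names misaligned")

    @property
    def is_ds_only(self) -> bool:
        return len(self.feature_names) == 1

    def to_json(self, path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "weights": [float(w) for w in self.weights],
            "bias": self.bias,
            "lambda": self.lambda_,
            "standardizer": (
                {"mu": self.standardizer.mu, "sigma": self.standardizer.sigma}
                if self.standardizer
                else None
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "TrainedClassifier":
        d = json.loads(Path(path).read_text())
        std = d["standardizer"]
        return cls(
            weights=np.asarray(d["weights"], float),
            bias=float(d["bias"]),
            lambda_=float(d["lambda"]),
            standardizer=ScoreStandardizer(**std) if std else None,
            feature_names=tuple(d["feature_names"]),
        )


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

def standardize_scores(ds: Sequence[float], std: ScoreStandardizer) -> np.ndarray:
    return std.transform(ds)


def build_features(
    ds_st: pd.Series | Sequence[float],
    if_table: pd.DataFrame | None = None,
    compound_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble feature rows: DSst alone, or DSst + fingerprint bits in -1/+1.

    Rows are aligned by compound_id when both tables are indexed; a compound
    present in one table but not the other is an error.
    """
    if isinstance(ds_st, pd.Series):
        ds = ds_st.astype(float)
    else:
        if compound_ids is None:
            compound_ids = [f"c{i}" for i in range(len(ds_st))]
        ds = pd.Series(np.asarray(ds_st, float), index=list(compound_ids))
    X = ds.to_frame("ds_st")
    if if_table is not None:
        missing_if = sorted(set(X.index) - set(if_table.index))
        missing_ds = sorted(set(if_table.index) - set(X.index))
        if missing_if or missing_ds:
            raise ValueError(
                f"compound mismatch: no fingerprint for {missing_if}; "
                f"no score for {missing_ds}"
            )
        bits = if_table.loc[X.index]
        bad = bits.values[(bits.values != 0) & (bits.values != 1)]
        if bad.size:
            raise ValueError("fingerprint table must be binary 0/1")
        X = pd.concat([X, 2.0 * bits - 1.0], axis=1)
    return X


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _fit_at_lambda(X: np.ndarray, y: np.ndarray, lam: float, seed: int) -> LinearSVC:
    # lambda in (0,1) maps onto the whole regularization path: the effective
    # L1 weight is lam/(1-lam) per mean loss, so lam -> 1 yields the empty
    # model and lam -> 0 the unpenalized fit; liblinear C = (1-lam)/(n*lam)
    C = (1.0 - lam) / (len(y) * lam)
    clf = LinearSVC(
        penalty="l1",
        loss="squared_hinge",
        dual=False,
        C=C,
        tol=1e-6,
        max_iter=10_000,
        random_state=seed,
    )
    clf.fit(X, y)
    return clf


def fit_at_lambda(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence[int],
    lambda_: float,
    seed: int = 0,
    standardizer: ScoreStandardizer | None = None,
) -> TrainedClassifier:
    """Fit at a fixed regularization strength, skipping grid selection."""
    if isinstance(features, pd.DataFrame):
        names = tuple(features.columns)
        X = features.to_numpy(float)
    else:
        X = np.asarray(features, float)
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    clf = _fit_at_lambda(X, np.asarray(labels, int), lambda_, seed)
    return TrainedClassifier(
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        lambda_=lambda_,
        standardizer=standardizer,
        feature_names=names,
    )


def train_l1_svm(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence[int],
    cfg: RegularizationConfig = RegularizationConfig(),
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    standardizer: ScoreStandardizer | None = None,
) -> TrainedClassifier:
    """Fit an L1 linear SVM per lambda on the grid, pick the lambda with the
    lowest error on a stratified held-out tuning split (ties -> sparser,
    i.e. larger lambda), then refit on the full training set."""
    if isinstance(features, pd.DataFrame):
        names = tuple(features.columns)
        X = features.to_numpy(float)
    else:
        X = np.asarray(features, float)
        names = tuple(
            feature_names
            if feature_names is not None
            else (f"x{i}" for i in range(X.shape[1]))
        )
    y = np.asarray(labels, int)
    if set(np.unique(y)) != {BINDER_CLASS, NONBINDER_CLASS}:
        raise ValueError("training labels must contain both classes (+1/-1)")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")

    X_fit, X_tune, y_fit, y_tune = train_test_split(
        X, y, test_size=cfg.tuning_fraction, stratify=y, random_state=seed
    )
    best_lam, best_err = None, math.inf
    for lam in sorted(cfg.lambda_grid):
        clf = _fit_at_lambda(X_fit, y_fit, lam, seed)
        err = float(np.mean(clf.predict(X_tune) != y_tune))
        if err < best_err or (err == best_err and best_lam is not None):
            # '<=' keeps the largest (sparsest) lambda among ties
            best_lam, best_err = lam, err
    final = _fit_at_lambda(X, y, best_lam, seed)
    return TrainedClassifier(
        weights=final.coef_.ravel().copy(),
        bias=float(final.intercept_[0]),
        lambda_=best_lam,
        standardizer=standardizer,
        feature_names=names,
    )


def predict(
    model: TrainedClassifier, features: pd.DataFrame | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels (+1 binder / -1 nonbinder) and signed margins w.x + b.

    A margin of exactly zero is called nonbinder: for an antitarget it is
    safer to flag the compound for experimental follow-up than to certify it.
    """
    if isinstance(features, pd.DataFrame):
        if tuple(features.columns) != model.feature_names:
            raise ValueError(
                f"feature columns {tuple(features.columns)} do not match "
                f"training columns {model.feature_names}"
            )
        X = features.to_numpy(float)
    else:
        X = np.asarray(features, float)
        if X.shape[1] != len(model.feature_names):
            raise ValueError("feature count mismatch")
    margins = X @ model.weights + model.bias
    labels = np.where(margins > 0, BINDER_CLASS, NONBINDER_CLASS)
    return labels, margins
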