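"""Classifier comparison over repeated shared stratified splits.

Each of ``n_seeds`` seeds produces one stratified 80/20 split shared by every
(method, feature set) pair, so accuracy differences are paired by data
division.  Reported per pair: average classification accuracy (ACA), sample
variance, and a t-interval on the mean; pairs of accuracy vectors are
compared with a paired t-test (Welch available for unpaired designs).

Built-in methods: MLR (unpenalized), MLR-R (ridge, CV λ), MLR-L (lasso, CV
λ), MLR-EN (CV α and λ), plus thin adapters over scikit-learn for the RF /
SVM / NB comparison baselines.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .cohort import ExpressionCohort
from .penalized_mlr import PenaltyConfig, fit_mlr_en, predict_class, select_params
from .sampling import SplitResult, stratified_split

Predictor = Callable[[np.ndarray, np.ndarray, np.ndarray, int], np.ndarray]
# signature: (X_train, y_train, X_test, seed) -> predicted labels


def _mlr_predictor(alpha_grid: tuple[float, ...] | None, config: PenaltyConfig) -> Predictor:
    """MLR family: λ (and α for the EN variant) by CV; λ=0 when grid is None."""

    def predict(X_tr, y_tr, X_te, seed):
        if alpha_grid is None:
            model = fit_mlr_en(X_tr, y_tr, alpha=0.0, lam=0.0, config=config)
        else:
            cfg = replace(config, alpha_grid=alpha_grid)
            alpha0, lambda0 = select_params(X_tr, y_tr, cfg, seed=seed)
            model = fit_mlr_en(X_tr, y_tr, alpha0, lambda0, cfg)
        return predict_class(model, X_te)

    return predict


def _sklearn_predictor(factory: Callable[[int], object]) -> Predictor:
    def predict(X_tr, y_tr, X_te, seed):
        clf = factory(seed)
        clf.fit(X_tr, y_tr)
        return np.asarray(clf.predict(X_te))

    return predict


def builtin_methods(config: PenaltyConfig = PenaltyConfig()) -> dict[str, Predictor]:
    return {
        "mlr": _mlr_predictor(None, config),
        "mlr-r": _mlr_predictor((0.0,), config),
        "mlr-l": _mlr_predictor((1.0,), config),
        "mlr-en": _mlr_predictor(tuple(config.alpha_grid), config),
        "rf": _sklearn_predictor(
            lambda seed: RandomForestClassifier(
                n_estimators=500, random_state=seed % (2**31)
            )
        ),
        "svm": _sklearn_predictor(lambda seed: SVC(random_state=seed % (2**31))),
        "nb": _sklearn_predictor(lambda seed: GaussianNB()),
    }


@dataclass
class ComparisonReport:
    """Accuracy vectors and summary statistics per (method, feature set)."""

    accuracies: dict[tuple[str, str], np.ndarray]
    summary: pd.DataFrame  # method, feature_set, aca, variance, ci_low, ci_high
    split_hashes: list[str]  # one per seed; identical across all pairs

    def accuracy_vector(self, method: str, feature_set: str) -> np.ndarray:
        return self.accuracies[(method, feature_set)]


def _split_hash(split: SplitResult) -> str:
    h = hashlib.sha256()
    h.update(split.train_indices.tobytes())
    h.update(split.test_indices.tobytes())
    return h.hexdigest()[:16]


def aca_ci(
    accuracies: Sequence[float], level: float = 0.95
) -> tuple[float, float, float, float]:
    """Mean, sample variance, and t-interval on the mean accuracy."""
    acc = np.asarray(accuracies, dtype=float)
    n = acc.size
    if n < 2:
        raise ValueError("need at least 2 accuracy values")
    mean = float(acc.mean())
    var = float(acc.var(ddof=1))
    half = float(stats.t.ppf(0.5 + level / 2, n - 1) * np.sqrt(var / n))
    return mean, var, mean - half, mean + half


def method_ttest(
    acc_a: Sequence[float], acc_b: Sequence[float], paired: bool = True
) -> tuple[float, float]:
    """Two-sided t-test between accuracy vectors; paired by shared seed.

    Degenerate zero-variance cases are guarded: identical vectors give
    (0.0, 1.0); a constant nonzero paired shift gives (±inf, 0.0), each with
    a warning.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test needs equal-length vectors")
        d = a - b
        if np.allclose(d.std(ddof=0), 0.0):
            if np.allclose(d, 0.0):
                warnings.warn("identical accuracy vectors; returning p = 1")
                return 0.0, 1.0
            warnings.warn("constant nonzero difference; returning p = 0")
            return float(np.sign(d.mean()) * np.inf), 0.0
        res = stats.ttest_rel(a, b)
    else:
        if a.std(ddof=0) == 0.0 and b.std(ddof=0) == 0.0:
            same = np.allclose(a.mean(), b.mean())
            warnings.warn("zero-variance samples in Welch test; guarded result")
            return (0.0, 1.0) if same else (float("inf"), 0.0)
        res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def compare_methods(
    cohort: ExpressionCohort,
    feature_sets: Mapping[str, Sequence[str]],
    methods: Sequence[str] | Mapping[str, Predictor],
    n_seeds: int = 100,
    train_frac: float = 0.8,
    config: PenaltyConfig = PenaltyConfig(),
) -> ComparisonReport:
    """Evaluate every (method, feature set) pair on ``n_seeds`` shared splits.

    Validates all method and feature names before any training; seeds run
    1..n_seeds, and within one seed every pair sees identical train/test
    indices.
    """
    registry = builtin_methods(config)
    if isinstance(methods, Mapping):
        resolved: dict[str, Predictor] = dict(methods)
    else:
        unknown = [m for m in methods if m not in registry]
        if unknown:
            raise ValueError(
                f"unknown methods {unknown}; available: {sorted(registry)}"
            )
        resolved = {m: registry[m] for m in methods}
    feature_cols: dict[str, list[int]] = {}
    for name, feats in feature_sets.items():
        feature_cols[name] = [cohort.feature_index(f) for f in feats]

    accuracies = {
        (m, fs): np.empty(n_seeds) for m in resolved for fs in feature_sets
    }
    split_hashes: list[str] = []
    for s in range(1, n_seeds + 1):
        split = stratified_split(cohort.labels, train_frac=train_frac, seed=s)
        split_hashes.append(_split_hash(split))
        y_tr = cohort.labels[split.train_indices]
        y_te = cohort.labels[split.test_indices]
        for fs_name, cols in feature_cols.items():
            X_tr = cohort.values[np.ix_(split.train_indices, cols)]
            X_te = cohort.values[np.ix_(split.test_indices, cols)]
            for m_name, predictor in resolved.items():
                pred = predictor(X_tr, y_tr, X_te, s)
                accuracies[(m_name, fs_name)][s - 1] = np.mean(pred == y_te)

    rows = []
    for (m_name, fs_name), acc in accuracies.items():
        if n_seeds >= 2:
            mean, var, lo, hi = aca_ci(acc)
        else:
            mean, var, lo, hi = float(acc.mean()), float("nan"), float("nan"), float("nan")
        rows.append(
            {
                "method": m_name,
                "feature_set": fs_name,
                "aca": mean,
                "variance": var,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return ComparisonReport(
        accuracies=accuracies,
        summary=pd.DataFrame(rows),
        split_hashes=split_hashes,
    )
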