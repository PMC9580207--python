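"""Bootstrap ensemble of MLR-EN models: training, voting, scoring, seed search.

For one stratified split, M models are each fit on a fresh per-subtype
bootstrap resample of the training set, with (α₀, λ₀) re-selected by
cross-validation on that resample.  Test samples are classified by majority
vote; the vote fraction of the true class feeds a floored cross-entropy
(probability floor 0.001 so zero-vote classes stay finite).  The seed search
repeats split → ensemble → score over seeds 1..n_repeats and keeps the split
with the highest accuracy (ties: lowest cross-entropy) for feature screening.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort, N_CLASSES
from .penalized_mlr import MlrModel, PenaltyConfig, fit_mlr_en, predict_class, select_params
from .sampling import SplitResult, bootstrap_per_subtype, derived_seed, stratified_split

log = logging.getLogger(__name__)

ALL_CLASSES = np.arange(1, N_CLASSES + 1)


class EnsembleError(RuntimeError):
    """Ensemble-level failure, annotated with the replicate index."""


@dataclass
class EnsembleResult:
    """M fitted models sharing one split, plus the test-set vote tally."""

    models: list[MlrModel]
    split: SplitResult
    vote_matrix: np.ndarray  # n_test × 5 ints, rows sum to M
    M: int

    def __post_init__(self) -> None:
        if len(self.models) != self.M:
            raise EnsembleError(f"expected {self.M} models, got {len(self.models)}")
        self.vote_matrix = np.asarray(self.vote_matrix, dtype=int)
        if self.vote_matrix.size and not (self.vote_matrix.sum(axis=1) == self.M).all():
            raise EnsembleError("vote rows must sum to M")


def _votes(models: list[MlrModel], X: np.ndarray) -> np.ndarray:
    votes = np.zeros((X.shape[0], N_CLASSES), dtype=int)
    for model in models:
        pred = predict_class(model, X)
        for j, code in enumerate(ALL_CLASSES):
            votes[pred == code, j] += 1
    return votes


def train_ensemble(
    cohort: ExpressionCohort,
    split: SplitResult,
    M: int = 100,
    config: PenaltyConfig = PenaltyConfig(),
    seed: int = 0,
) -> EnsembleResult:
    """Fit M MLR-EN models on per-subtype bootstrap resamples of the split.

    Replicate m draws its bootstrap and CV seeds from (seed, m) so any single
    replicate is reproducible in isolation.
    """
    models: list[MlrModel] = []
    for m in range(M):
        try:
            idx = bootstrap_per_subtype(
                split, cohort.labels, derived_seed(seed, m, 0)
            )
            Xb, yb = cohort.values[idx], cohort.labels[idx]
            alpha0, lambda0 = select_params(
                Xb, yb, config, seed=derived_seed(seed, m, 1)
            )
            models.append(fit_mlr_en(Xb, yb, alpha0, lambda0, config))
        except Exception as exc:  # annotate with the replicate index
            raise EnsembleError(f"replicate {m} failed: {exc}") from exc
    votes = _votes(models, cohort.values[split.test_indices])
    return EnsembleResult(models=models, split=split, vote_matrix=votes, M=M)


def vote_predict(
    ensemble: EnsembleResult, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote labels and vote fractions (rows sum to 1).

    Ties resolve to the smallest class code.
    """
    if not ensemble.models:
        raise EnsembleError("empty ensemble")
    votes = _votes(ensemble.models, np.asarray(X, dtype=float))
    labels = ALL_CLASSES[np.argmax(votes, axis=1)]
    return labels, votes / ensemble.M


def cross_entropy(
    vote_fractions: np.ndarray,
    true_labels: np.ndarray,
    floor: float = 0.001,
    base: str = "e",
) -> float:
    """Mean −log of the true-class vote fraction, floored at ``floor``.

    The floor keeps samples whose true class received zero votes finite
    (−log 0.001 ≈ 6.9078 with the natural log, the default base).
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    fr = np.asarray(vote_fractions, dtype=float)
    y = np.asarray(true_labels, dtype=int)
    if np.any(y < 1) or np.any(y > N_CLASSES):
        raise ValueError(f"labels must lie in 1..{N_CLASSES}")
    p_true = fr[np.arange(fr.shape[0]), y - 1]
    logs = np.log(np.maximum(p_true, floor))
    if base == "2":
        logs = logs / np.log(2.0)
    elif base != "e":
        raise ValueError("base must be 'e' or '2'")
    return float(-np.mean(logs))


@dataclass
class SeedSearchResult:
    """Per-seed accuracy/cross-entropy table and the winning seed."""

    per_seed: list[tuple[int, float, float]]  # (seed, accuracy, cross_entropy)
    best_seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_seed, columns=["seed", "accuracy", "cross_entropy"]
        )


def _evaluate_split(
    cohort: ExpressionCohort,
    split: SplitResult,
    M: int,
    config: PenaltyConfig,
    seed: int,
) -> tuple[float, float]:
    """Train an ensemble on the split and score it on the held-out samples."""
    ensemble = train_ensemble(cohort, split, M=M, config=config, seed=seed)
    X_test = cohort.values[split.test_indices]
    y_test = cohort.labels[split.test_indices]
    labels, fractions = vote_predict(ensemble, X_test)
    accuracy = float(np.mean(labels == y_test))
    ce = cross_entropy(fractions, y_test)
    return accuracy, ce


def seed_search(
    cohort: ExpressionCohort,
    n_repeats: int = 50,
    M: int = 100,
    config: PenaltyConfig = PenaltyConfig(),
    train_frac: float = 0.8,
    evaluate: Callable[..., tuple[float, float]] | None = None,
) -> SeedSearchResult:
    """Repeat split → ensemble → score for seeds 1..n_repeats; keep the best.

    Best seed maximizes test accuracy; ties break toward the lower
    cross-entropy.  A failed repeat is recorded as NaN and skipped with a
    warning, never silently dropped.  ``evaluate`` may replace the default
    train-and-score routine (used for stubbing in tests).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    evaluate = evaluate or _evaluate_split
    records: list[tuple[int, float, float]] = []
    for r in range(1, n_repeats + 1):
        split = stratified_split(cohort.labels, train_frac=train_frac, seed=r)
        try:
            accuracy, ce = evaluate(cohort, split, M, config, r)
        except Exception as exc:
            warnings.warn(f"seed {r} failed and was skipped: {exc}", stacklevel=2)
            records.append((r, float("nan"), float("nan")))
            continue
        log.info("seed %d: accuracy=%.4f cross_entropy=%.4f", r, accuracy, ce)
        records.append((r, accuracy, ce))
    valid = [rec for rec in records if not np.isnan(rec[1])]
    if not valid:
        raise EnsembleError("every seed-search repeat failed")
    best_seed = min(valid, key=lambda rec: (-rec[1], rec[2], rec[0]))[0]
    return SeedSearchResult(per_seed=records, best_seed=best_seed)
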