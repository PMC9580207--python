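"""The samples × features expression container shared by every pipeline stage.

A cohort bundles a log2-scale (or raw) expression matrix with per-sample
subtype labels and right-censored survival records.  Subtypes follow the
standard breast-cancer intrinsic classification — Luminal A (LA), Luminal B
(LB), HER2-enriched (H2), Basal-like (BL) — plus a fifth "control" class for
normal tissue, coded 1..5 in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

SUBTYPES: tuple[str, ...] = ("LA", "LB", "H2", "BL", "control")
SUBTYPE_CODES: dict[str, int] = {name: i + 1 for i, name in enumerate(SUBTYPES)}
CODE_TO_SUBTYPE: dict[int, str] = {v: k for k, v in SUBTYPE_CODES.items()}
N_CLASSES = len(SUBTYPES)


class CohortError(ValueError):
    """Invalid cohort construction or access."""


@dataclass
class SurvivalRecords:
    """Right-censored follow-up: event time and status (1 = death, 0 = censored)."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape or self.time.ndim != 1:
            raise CohortError("time and event must be aligned 1-d arrays")
        if np.any(self.time < 0) or np.any(np.isnan(self.time)):
            raise CohortError("survival times must be finite and non-negative")
        if not np.isin(self.event, (0, 1)).all():
            raise CohortError("event indicator must be 0 (censored) or 1 (death)")

    def __len__(self) -> int:
        return self.time.shape[0]


@dataclass
class ExpressionCohort:
    """Expression matrix plus labels and (optional) survival follow-up.

    Parameters
    ----------
    sample_ids, feature_ids
        Unique row / column identifiers.
    values
        ``n_samples × n_features`` real matrix.  ``log_scale=True`` marks
        log2-transformed data ready for modelling; raw non-negative counts
        carry ``log_scale=False`` and must pass through
        :func:`mirsel.data_io.preprocess` first.
    labels
        Per-sample subtype code in 1..5 (see :data:`SUBTYPE_CODES`).
    survival
        Optional :class:`SurvivalRecords` aligned to ``sample_ids``.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    survival: SurvivalRecords | None = None
    log_scale: bool = True

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, p = len(self.sample_ids), len(self.feature_ids)
        if len(set(self.sample_ids)) != n:
            raise CohortError("duplicate sample IDs")
        if len(set(self.feature_ids)) != p:
            raise CohortError("duplicate feature IDs")
        if self.values.shape != (n, p):
            raise CohortError(
                f"values shape {self.values.shape} does not match "
                f"{n} samples × {p} features"
            )
        if self.labels.shape != (n,):
            raise CohortError("labels not aligned to sample_ids")
        if not np.isin(self.labels, list(CODE_TO_SUBTYPE)).all():
            raise CohortError(f"labels must be codes in {sorted(CODE_TO_SUBTYPE)}")
        if self.survival is not None and len(self.survival) != n:
            raise CohortError("survival records not aligned to sample_ids")
        if self.log_scale and not np.isfinite(self.values).all():
            raise CohortError("log-scale cohort contains non-finite values")
        self._feature_index = {f: k for k, f in enumerate(self.feature_ids)}

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self._feature_index[feature_id]
        except KeyError:
            raise CohortError(f"unknown feature {feature_id!r}") from None

    # -- views -------------------------------------------------------------
    def subset_samples(self, indices: Sequence[int]) -> "ExpressionCohort":
        """Row-subset view (copies); survival travels with the samples."""
        idx = np.asarray(indices, dtype=int)
        surv = None
        if self.survival is not None:
            surv = SurvivalRecords(self.survival.time[idx], self.survival.event[idx])
        # bootstrap resamples repeat rows, so IDs are disambiguated on demand
        ids = [self.sample_ids[i] for i in idx]
        if len(set(ids)) != len(ids):
            ids = [f"{s}#{j}" for j, s in enumerate(ids)]
        return ExpressionCohort(
            sample_ids=ids,
            feature_ids=list(self.feature_ids),
            values=self.values[idx],
            labels=self.labels[idx],
            survival=surv,
            log_scale=self.log_scale,
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionCohort":
        cols = [self.feature_index(f) for f in feature_ids]
        return replace(
            self,
            feature_ids=[self.feature_ids[c] for c in cols],
            values=self.values[:, cols],
        )

    def feature_values(self, feature_id: str) -> np.ndarray:
        return self.values[:, self.feature_index(feature_id)]

    def subtype_counts(self) -> dict[int, int]:
        codes, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(codes.tolist(), counts.tolist()))
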