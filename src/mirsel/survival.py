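"""Kaplan–Meier / log-rank survival analysis and expression difference tests.

Samples are split into high/low expression groups at the feature's median
(ties to the low group), each group gets a product-limit survival estimate,
and a two-group log-rank test scores the separation.  Expression differences
between two subtypes use the two-sided Wilcoxon rank-sum test by default
(Welch t-test available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .cohort import SUBTYPE_CODES, CohortError, ExpressionCohort


class DegenerateSplitError(ValueError):
    """The expression cutoff left one group empty."""


@dataclass
class KMResult:
    """High/low group assignment, per-group survival steps, log-rank test."""

    assignment: np.ndarray  # "high"/"low" per sample
    times: dict[str, np.ndarray]
    survival: dict[str, np.ndarray]
    statistic: float
    p_value: float


def km_logrank(
    cohort: ExpressionCohort, feature_id: str, cutoff: str = "median"
) -> KMResult:
    """Median-split K–M curves and log-rank p for one feature."""
    if cohort.survival is None:
        raise CohortError("cohort has no survival records")
    if cohort.survival.event.sum() < 1:
        raise CohortError("no events observed")
    if cutoff != "median":
        raise ValueError("only the median cutoff is supported")
    x = cohort.feature_values(feature_id)
    high = x > np.median(x)
    if high.all() or not high.any():
        raise DegenerateSplitError(
            f"median split of {feature_id!r} leaves an empty group"
        )
    assignment = np.where(high, "high", "low")

    times: dict[str, np.ndarray] = {}
    survival: dict[str, np.ndarray] = {}
    for name, mask in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter()
        km.fit(cohort.survival.time[mask], cohort.survival.event[mask])
        sf = km.survival_function_
        times[name] = sf.index.to_numpy(dtype=float)
        survival[name] = sf.iloc[:, 0].to_numpy(dtype=float)

    res = logrank_test(
        cohort.survival.time[high],
        cohort.survival.time[~high],
        event_observed_A=cohort.survival.event[high],
        event_observed_B=cohort.survival.event[~high],
    )
    return KMResult(
        assignment=assignment,
        times=times,
        survival=survival,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
    )


def expression_diff_test(
    cohort: ExpressionCohort,
    feature_id: str,
    subtype_a: str | int,
    subtype_b: str | int,
    test: str = "ranksum",
) -> tuple[float, float]:
    """Two-sided test of expression difference between two subtype groups."""
    def code(s):
        return SUBTYPE_CODES[s] if isinstance(s, str) else int(s)

    x = cohort.feature_values(feature_id)
    a = x[cohort.labels == code(subtype_a)]
    b = x[cohort.labels == code(subtype_b)]
    if a.size == 0 or b.size == 0:
        raise CohortError("empty subtype group in expression test")
    if test == "ranksum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "ttest":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError("test must be 'ranksum' or 'ttest'")
    return float(res.statistic), float(min(res.pvalue, 1.0))
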