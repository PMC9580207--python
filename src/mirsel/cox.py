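"""Cox proportional-hazards biomarker filtering on a selected feature panel.

One multivariate Cox PH model is fit jointly over every panel feature
(hazard h(t) = h₀(t)·exp(β₁x₁ + … + β_p x_p)); ties in event times use the
Efron approximation, p-values are Wald.  Features with |β| > 0.2 and
p < 0.05 are flagged as biomarkers; exp(β) is the per-unit hazard ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError as _LifelinesConvergence

from .cohort import CohortError, ExpressionCohort
from .feature_selection import FeaturePanel

DEFAULT_COEF_THRESH = 0.2
DEFAULT_P_THRESH = 0.05


class CoxFitError(RuntimeError):
    """Cox model could not be fit."""


@dataclass
class CoxBiomarkerReport:
    """Per-feature Cox coefficient, hazard ratio, Wald p, and biomarker flag."""

    table: pd.DataFrame  # feature_id, beta, hazard_ratio, p_value, is_biomarker
    coef_thresh: float | None = None
    p_thresh: float | None = None

    REQUIRED = ("feature_id", "beta", "hazard_ratio", "p_value", "is_biomarker")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"report table missing columns {missing}")

    @property
    def biomarkers(self) -> list[str]:
        flagged = self.table[self.table["is_biomarker"]]
        return flagged["feature_id"].tolist()

    def write(self, path: str | Path) -> None:
        cols = ["feature_id", "beta", "hazard_ratio", "p_value", "is_biomarker"]
        self.table[cols].rename(columns={"beta": "cox_coefficient"}).to_csv(
            path, sep="\t", index=False
        )


def hazard_ratio(beta: float) -> float:
    """exp(β): >1 increases, <1 decreases the instantaneous risk of death."""
    return math.exp(beta)


def fit_cox(
    cohort: ExpressionCohort,
    panel: FeaturePanel | Iterable[str],
    ridge: float = 0.0,
) -> CoxBiomarkerReport:
    """Joint multivariate Cox PH fit over all panel features (Efron ties).

    ``ridge`` adds an L2 penalizer for ill-conditioned panels (off by
    default); covariates enter on their native log2 scale, so the 0.2
    coefficient threshold keeps its published meaning.
    """
    features = (
        panel.selected_sorted if isinstance(panel, FeaturePanel) else list(panel)
    )
    if not features:
        raise CoxFitError("empty feature panel")
    if cohort.survival is None:
        raise CohortError("cohort has no survival records")
    if cohort.survival.event.sum() < 1:
        raise CoxFitError("no events observed; all samples censored")
    sub = cohort.subset_features(features)
    sd = sub.values.std(axis=0)
    dead = [f for f, s in zip(features, sd) if s < 1e-12]
    if dead:
        raise CoxFitError(f"zero-variance covariates: {dead}")

    df = pd.DataFrame(sub.values, columns=features)
    df["time"] = cohort.survival.time
    df["event"] = cohort.survival.event
    fitter = CoxPHFitter(penalizer=ridge)
    try:
        fitter.fit(df, duration_col="time", event_col="event")
    except (_LifelinesConvergence, np.linalg.LinAlgError) as exc:
        raise CoxFitError(
            "Cox fit did not converge; consider the ridge stabilization "
            "flag (e.g. ridge=0.1)"
        ) from exc
    summary = fitter.summary
    table = pd.DataFrame(
        {
            "feature_id": summary.index,
            "beta": summary["coef"].to_numpy(),
            "hazard_ratio": np.exp(summary["coef"].to_numpy()),
            "p_value": summary["p"].to_numpy(),
            "is_biomarker": False,
        }
    ).reset_index(drop=True)
    return CoxBiomarkerReport(table=table)


def filter_biomarkers(
    report: CoxBiomarkerReport,
    coef_thresh: float = DEFAULT_COEF_THRESH,
    p_thresh: float = DEFAULT_P_THRESH,
) -> CoxBiomarkerReport:
    """Flag rows with |β| > coef_thresh and p < p_thresh (strict inequalities).

    Rows are returned sorted by |β| descending.
    """
    table = report.table.copy()
    table["is_biomarker"] = (np.abs(table["beta"]) > coef_thresh) & (
        table["p_value"] < p_thresh
    )
    table = table.reindex(
        table["beta"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
    return CoxBiomarkerReport(
        table=table, coef_thresh=coef_thresh, p_thresh=p_thresh
    )
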