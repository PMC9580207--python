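"""Reading, writing, and preprocessing of the three pipeline input tables.

All tables are UTF-8 TSV with a header row:

* expression — rows = samples, columns = features; first column ``sample_id``;
* labels — columns ``sample_id``, ``subtype`` (LA/LB/H2/BL/control);
* clinical — columns ``sample_id``, ``time``, ``event`` (1 = death, 0 = censored).

Preprocessing mirrors the standard miRNA-seq cleanup for this kind of cohort:
drop features whose fraction of non-expressed entries (value ≤ 0 or missing)
exceeds 1%, then move to the log2 scale.
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .cohort import SUBTYPE_CODES, CODE_TO_SUBTYPE, CohortError, ExpressionCohort, SurvivalRecords


class AlignmentError(CohortError):
    """Sample IDs do not line up across the input tables."""


class ParseError(CohortError):
    """A table cell could not be interpreted."""


class ScaleError(CohortError):
    """Operation applied to data on the wrong scale."""


class EmptyPanelError(CohortError):
    """A filtering step removed every feature."""


def _read_tsv(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so written values reload bit-identically
    return pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")


def load_cohort(
    expression_path: str | Path,
    labels_path: str | Path,
    clinical_path: str | Path | None = None,
    log_scale: bool = True,
) -> ExpressionCohort:
    """Load and align the three input tables; row order follows the expression file.

    Set ``log_scale=False`` for raw (pre-:func:`preprocess`) expression values.
    """
    expr = _read_tsv(expression_path)
    sample_col = expr.columns[0]
    sample_ids = expr[sample_col].astype(str).tolist()
    feature_ids = [str(c) for c in expr.columns[1:]]
    value_df = expr.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    raw_obj = expr.iloc[:, 1:]
    bad = value_df.isna() & raw_obj.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric expression value {raw_obj.iat[r, c]!r} at "
            f"sample {sample_ids[r]!r}, feature {feature_ids[c]!r}"
        )
    values = value_df.to_numpy(dtype=float)

    labels_df = _read_tsv(labels_path).set_index("sample_id")
    missing = sorted(set(sample_ids) - set(labels_df.index))
    if missing:
        raise AlignmentError(f"labels file is missing samples: {missing}")
    subtype = labels_df.loc[sample_ids, "subtype"]
    unknown = sorted(set(subtype) - set(SUBTYPE_CODES))
    if unknown:
        raise ParseError(f"unknown subtype labels: {unknown}")
    labels = np.array([SUBTYPE_CODES[s] for s in subtype], dtype=int)

    survival = None
    if clinical_path is not None:
        clin = _read_tsv(clinical_path).set_index("sample_id")
        missing = sorted(set(sample_ids) - set(clin.index))
        if missing:
            raise AlignmentError(f"clinical file is missing samples: {missing}")
        clin = clin.loc[sample_ids]
        event = pd.to_numeric(clin["event"], errors="coerce").to_numpy()
        if np.isnan(event).any() or not np.isin(event, (0, 1)).all():
            raise ParseError("clinical 'event' must be 0 or 1 for every sample")
        time = pd.to_numeric(clin["time"], errors="coerce").to_numpy(dtype=float)
        if np.isnan(time).any():
            raise ParseError("clinical 'time' must be numeric for every sample")
        survival = SurvivalRecords(time=time, event=event.astype(int))

    return ExpressionCohort(
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        values=values,
        labels=labels,
        survival=survival,
        log_scale=log_scale,
    )


def write_cohort(cohort: ExpressionCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write expression/labels(/clinical) TSVs; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    expr = pd.DataFrame(cohort.values, columns=cohort.feature_ids)
    expr.insert(0, "sample_id", cohort.sample_ids)
    paths["expression"] = out / "expression.tsv"
    expr.to_csv(paths["expression"], sep="\t", index=False, float_format="%.17g")

    labels = pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "subtype": [CODE_TO_SUBTYPE[c] for c in cohort.labels],
        }
    )
    paths["labels"] = out / "labels.tsv"
    labels.to_csv(paths["labels"], sep="\t", index=False)

    if cohort.survival is not None:
        clin = pd.DataFrame(
            {
                "sample_id": cohort.sample_ids,
                "time": cohort.survival.time,
                "event": cohort.survival.event,
            }
        )
        paths["clinical"] = out / "clinical.tsv"
        clin.to_csv(paths["clinical"], sep="\t", index=False, float_format="%.17g")
    return paths


class PreprocessResult(NamedTuple):
    cohort: ExpressionCohort
    removed_features: list[str]


def preprocess(
    raw: ExpressionCohort, max_nonexpressed_frac: float = 0.01
) -> PreprocessResult:
    """Drop scarcely expressed features and log2-transform the remainder.

    A cell is *non-expressed* when its value is ≤ 0 or missing.  A feature is
    removed when its non-expressed fraction is strictly greater than
    ``max_nonexpressed_frac`` (so exactly 1% of zeros survives the default
    cutoff).  Retained values become ``log2(x + 1)`` — the pseudo-count keeps
    the ≤1% residual zeros finite — with missing entries treated as zeros.
    """
    if raw.log_scale:
        raise ScaleError(
            "preprocess expects raw-scale expression (construct the cohort "
            "with log_scale=False); data is already log2-transformed"
        )
    values = raw.values
    nonexpr = np.isnan(values) | (values <= 0)
    frac = nonexpr.mean(axis=0)
    keep = frac <= max_nonexpressed_frac
    removed = [f for f, k in zip(raw.feature_ids, keep) if not k]
    if not keep.any():
        raise EmptyPanelError("preprocessing removed every feature")
    kept_values = np.where(np.isnan(values[:, keep]), 0.0, values[:, keep])
    transformed = np.log2(np.maximum(kept_values, 0.0) + 1.0)
    cohort = ExpressionCohort(
        sample_ids=list(raw.sample_ids),
        feature_ids=[f for f, k in zip(raw.feature_ids, keep) if k],
        values=transformed,
        labels=raw.labels.copy(),
        survival=raw.survival,
        log_scale=True,
    )
    return PreprocessResult(cohort=cohort, removed_features=removed)
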