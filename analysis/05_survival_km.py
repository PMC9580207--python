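#!/usr/bin/env python
"""Kaplan–Meier and expression analysis for the flagged biomarkers.

For each biomarker from 04_cox_biomarkers.py: split samples at the feature's
median expression, estimate K–M curves for the high/low groups, test the
separation with the log-rank test, and test control-vs-subtype expression
differences with the Wilcoxon rank-sum test.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from mirsel import (
    SUBTYPES,
    SimulationConfig,
    expression_diff_test,
    generate_cohort,
    km_logrank,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1, max_features: int = 5) -> None:
    cohort, _ = generate_cohort(SimulationConfig(seed=seed))
    biomarkers_path = RESULTS / "biomarkers.tsv"
    if not biomarkers_path.exists():
        sys.exit("run 04_cox_biomarkers.py first (biomarkers.tsv missing)")
    table = pd.read_csv(biomarkers_path, sep="\t")
    flagged = table.loc[table["is_biomarker"], "feature_id"].head(max_features)

    rows = []
    for feature in flagged:
        km = km_logrank(cohort, feature)
        row = {"feature_id": feature, "logrank_stat": km.statistic,
               "logrank_p": km.p_value}
        for subtype in SUBTYPES[:4]:
            _, p = expression_diff_test(cohort, feature, "control", subtype)
            row[f"p_control_vs_{subtype}"] = p
        rows.append(row)
        print(
            f"{feature}: log-rank stat {km.statistic:.3f}, p {km.p_value:.4g}"
        )

    frame = pd.DataFrame(rows)
    out = RESULTS / "km_expression_analysis.tsv"
    frame.to_csv(out, sep="\t", index=False)
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
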