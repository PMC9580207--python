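#!/usr/bin/env python
"""Promote the screened panel to biomarkers with a multivariate Cox filter.

Fits one Cox proportional-hazards model jointly over the panel written by
03_screen_features.py and flags features with |β| > 0.2 and p < 0.05,
reporting hazard ratios and comparing the flags against the planted
prognostic truth.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from mirsel import SimulationConfig, filter_biomarkers, fit_cox, generate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    cohort, truth = generate_cohort(SimulationConfig(seed=seed))
    panel_path = RESULTS / "feature_panel.tsv"
    if not panel_path.exists():
        sys.exit("run 03_screen_features.py first (feature_panel.tsv missing)")
    features = pd.read_csv(panel_path, sep="\t")["feature_id"].tolist()

    report = filter_biomarkers(fit_cox(cohort, features))
    out = RESULTS / "biomarkers.tsv"
    report.write(out)

    flagged = set(report.biomarkers)
    planted = set(truth.prognostic_features)
    print(report.table.to_string(index=False))
    print(
        f"\nflagged {len(flagged)} of {len(features)} panel features as "
        f"biomarkers (|β| > 0.2, p < 0.05)"
    )
    in_panel = planted & set(features)
    print(
        f"planted prognostic features: {len(planted)}; in panel: "
        f"{len(in_panel)}; flagged: {len(flagged & planted)}"
    )
    print(f"wrote {out}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
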