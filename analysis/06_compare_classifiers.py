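#!/usr/bin/env python
"""Compare classifiers on the screened panel versus the whole feature set.

Evaluates ridge multinomial regression plus the RF/SVM/NB baselines on
shared stratified splits (the same divisions for every method × feature-set
pair), reporting ACA, variance, and a 95% t-interval, plus a paired t-test
between the panel and the whole set for each method.  Seeds are scaled to 10
splits to keep the driver interactive.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from mirsel import SimulationConfig, compare_methods, generate_cohort, method_ttest
from mirsel.experiments import ENSEMBLE_CV

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1, n_seeds: int = 10) -> None:
    cohort, _ = generate_cohort(SimulationConfig(seed=seed))
    panel_path = RESULTS / "feature_panel.tsv"
    if not panel_path.exists():
        sys.exit("run 03_screen_features.py first (feature_panel.tsv missing)")
    panel = pd.read_csv(panel_path, sep="\t")["feature_id"].tolist()

    methods = ["mlr-r", "rf", "svm", "nb"]
    report = compare_methods(
        cohort,
        {"panel": panel, "all": list(cohort.feature_ids)},
        methods,
        n_seeds=n_seeds,
        config=ENSEMBLE_CV,
    )
    out = RESULTS / "classifier_comparison.tsv"
    report.summary.to_csv(out, sep="\t", index=False)
    print(report.summary.to_string(index=False))

    print("\npaired t-tests, panel vs all features:")
    for method in methods:
        t, p = method_ttest(
            report.accuracy_vector(method, "panel"),
            report.accuracy_vector(method, "all"),
            paired=True,
        )
        print(f"  {method}: t = {t:.3f}, p = {p:.4g}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
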