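#!/usr/bin/env python
"""Generate the synthetic study cohort and write its three input tables.

Emits a 231-sample × 296-feature log2 expression matrix with the study's
subtype sizes (86 LA, 39 LB, 24 H2, 41 BL, 41 control), planted multisubtype
signal, and right-censored survival.  The per-sample tables are large, so
they go under scratch/cohort/ (regenerated deterministically on demand);
the summary tables of later steps live under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from mirsel import SimulationConfig, generate_cohort, realized_censoring, write_cohort

OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"


def main(seed: int = 1) -> None:
    config = SimulationConfig(seed=seed)
    cohort, truth = generate_cohort(config)
    paths = write_cohort(cohort, OUT)
    truth.to_json(OUT / "ground_truth.json")

    print(f"cohort: {cohort.n_samples} samples x {cohort.n_features} features")
    print(f"subtype sizes: {cohort.subtype_counts()}")
    print(f"planted multisubtype features: {len(truth.multisubtype_features)}")
    print(f"planted prognostic features: {len(truth.prognostic_features)}")
    print(f"realized censoring: {realized_censoring(cohort):.3f} "
          f"(target {config.censoring_rate_target})")
    for name, path in paths.items():
        print(f"wrote {name}: {path}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
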