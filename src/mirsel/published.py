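"""Published multivariate Cox results for 22 miRNA biomarkers (TCGA BRCA).

Reference values reported for a 231-sample TCGA breast-invasive-carcinoma
miRNA-seq cohort: per-miRNA Cox coefficient, hazard ratio, and Wald p-value
from a joint proportional-hazards fit over a 124-miRNA panel, from which the
22 rows below were flagged at |β| > 0.2 and p < 0.05.  Used to validate
hazard-ratio arithmetic and the biomarker filter against externally printed
numbers.
"""

from __future__ import annotations

import pandas as pd

from .cox import CoxBiomarkerReport

# (miRNA, Cox coefficient, hazard ratio, p-value)
_ROWS = [
    ("hsa-miR-30e-3p", -0.3138, 0.7307, 0.0381),
    ("hsa-miR-1266-5p", 0.3046, 1.3561, 0.0007),
    ("hsa-miR-99b-5p", 0.2803, 1.3235, 0.0083),
    ("hsa-miR-629-5p", 0.2759, 1.3177, 0.0073),
    ("hsa-let-7e-5p", 0.2713, 1.3117, 0.0233),
    ("hsa-miR-27b-5p", 0.2526, 1.2873, 0.0177),
    ("hsa-let-7g-3p", 0.2497, 1.2836, 0.0032),
    ("hsa-miR-125a-3p", 0.2457, 1.2785, 0.0237),
    ("hsa-miR-193b-5p", 0.2344, 1.2642, 0.0035),
    ("hsa-miR-99b-3p", 0.2322, 1.2614, 0.0069),
    ("hsa-miR-744-5p", 0.2248, 1.2521, 0.0202),
    ("hsa-miR-29a-3p", -0.2247, 0.7988, 0.0249),
    ("hsa-miR-107", 0.2225, 1.2492, 0.0493),
    ("hsa-miR-130b-3p", 0.2215, 1.2479, 0.0015),
    ("hsa-miR-495-3p", -0.2202, 0.8024, 0.0031),
    ("hsa-miR-331-3p", 0.2149, 1.2397, 0.0157),
    ("hsa-miR-340-5p", 0.2145, 1.2392, 0.0306),
    ("hsa-miR-127-3p", -0.2130, 0.8082, 0.0017),
    ("hsa-miR-671-5p", 0.2089, 1.2323, 0.0114),
    ("hsa-miR-30a-5p", -0.2062, 0.8137, 0.0013),
    ("hsa-miR-452-5p", -0.2025, 0.8167, 3.09e-05),
    ("hsa-miR-889-3p", -0.2013, 0.8177, 0.0052),
]


def published_biomarker_table() -> pd.DataFrame:
    """The 22 published rows: miRNA, cox_coefficient, hazard_ratio, p_value."""
    return pd.DataFrame(
        _ROWS, columns=["miRNA", "cox_coefficient", "hazard_ratio", "p_value"]
    )


def published_biomarker_report() -> CoxBiomarkerReport:
    """The published rows wrapped as an (unfiltered) Cox report."""
    df = published_biomarker_table().rename(
        columns={"miRNA": "feature_id", "cox_coefficient": "beta"}
    )
    df["is_biomarker"] = False
    return CoxBiomarkerReport(table=df)
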