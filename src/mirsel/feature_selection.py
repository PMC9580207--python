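"""Frequency-based feature selection across the bootstrap ensemble.

For each feature k and subtype j, count in how many of the M models the
class-j coefficient of feature k is nonzero.  Features passing the count
threshold (default: at least half of the models) form the per-subtype sets
D_1..D_5; features appearing in at least ``min_subtypes`` of those sets
(default 3, i.e. at least half of the subtypes) form the selected panel D*.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import N_CLASSES
from .ensemble import EnsembleResult


@dataclass
class FrequencyTable:
    """Per-feature, per-subtype nonzero-coefficient counts across M models."""

    counts: np.ndarray  # p × 5 ints in [0, M]
    M: int
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.feature_ids), N_CLASSES):
            raise ValueError("counts must be n_features × 5")
        if self.counts.min() < 0 or self.counts.max() > self.M:
            raise ValueError("counts must lie in [0, M]")


@dataclass
class FeaturePanel:
    """Per-subtype selected sets D_j and the cross-subtype panel D*."""

    per_subtype_sets: dict[int, set[str]]
    selected: set[str]
    participation: dict[str, int]
    min_subtypes: int

    def __post_init__(self) -> None:
        union = set().union(*self.per_subtype_sets.values())
        if not self.selected <= union:
            raise ValueError("selected panel must be a subset of the D_j union")
        for f in self.selected:
            if self.participation.get(f, 0) < self.min_subtypes:
                raise ValueError(f"{f} selected with participation below threshold")

    @property
    def selected_sorted(self) -> list[str]:
        return sorted(self.selected)


def count_frequencies(
    ensemble: EnsembleResult,
    zero_tol: float = 0.0,
    feature_ids: list[str] | None = None,
) -> FrequencyTable:
    """C[k][j] = number of models with |coefficient(k, class j)| > zero_tol.

    The proximal solver emits exact zeros, so the default tolerance is 0;
    ``zero_tol`` accommodates dense solvers that only shrink toward zero.
    """
    if not ensemble.models:
        raise ValueError("empty ensemble")
    p = ensemble.models[0].n_features
    counts = np.zeros((p, N_CLASSES), dtype=int)
    for model in ensemble.models:
        nz = np.abs(model.coefficients) > zero_tol  # p × K
        cols = np.asarray(model.classes, dtype=int) - 1
        counts[:, cols] += nz.astype(int)
    if feature_ids is None:
        feature_ids = [f"f{k}" for k in range(p)]
    return FrequencyTable(counts=counts, M=ensemble.M, feature_ids=list(feature_ids))


def select_per_subtype(
    freq: FrequencyTable, threshold: int = 50, comparator: str = ">="
) -> dict[int, set[str]]:
    """D_j = features whose count for subtype j meets the threshold.

    The comparator defaults to ``>=`` (at least ``threshold`` of the M
    models); ``>`` is available as a strict alternative.
    """
    if not 0 <= threshold <= freq.M:
        raise ValueError(f"threshold must lie in [0, {freq.M}]")
    if comparator == ">=":
        hits = freq.counts >= threshold
    elif comparator == ">":
        hits = freq.counts > threshold
    else:
        raise ValueError("comparator must be '>=' or '>'")
    return {
        j + 1: {freq.feature_ids[k] for k in np.flatnonzero(hits[:, j])}
        for j in range(N_CLASSES)
    }


def select_features(
    per_subtype_sets: dict[int, set[str]], min_subtypes: int = 3
) -> FeaturePanel:
    """D* = features present in at least ``min_subtypes`` of the D_j sets."""
    if not 1 <= min_subtypes <= N_CLASSES:
        raise ValueError(f"min_subtypes must lie in 1..{N_CLASSES}")
    participation: dict[str, int] = {}
    for members in per_subtype_sets.values():
        for f in members:
            participation[f] = participation.get(f, 0) + 1
    selected = {f for f, c in participation.items() if c >= min_subtypes}
    return FeaturePanel(
        per_subtype_sets={j: set(s) for j, s in per_subtype_sets.items()},
        selected=selected,
        participation=participation,
        min_subtypes=min_subtypes,
    )


def subtype_participation_counts(panel: FeaturePanel) -> dict[int, int]:
    """|D_j| per subtype, for reporting."""
    return {j: len(s) for j, s in sorted(panel.per_subtype_sets.items())}


def panel_to_frame(
    panel: FeaturePanel, freq: FrequencyTable | None = None
) -> pd.DataFrame:
    """Selected panel as a table: feature, participation, per-subtype counts."""
    rows = []
    for f in panel.selected_sorted:
        row: dict[str, object] = {
            "feature_id": f,
            "participation": panel.participation[f],
        }
        if freq is not None:
            k = freq.feature_ids.index(f)
            for j in range(N_CLASSES):
                row[f"count_subtype_{j + 1}"] = int(freq.counts[k, j])
        rows.append(row)
    return pd.DataFrame(rows)


def write_panel(
    panel: FeaturePanel, path: str | Path, freq: FrequencyTable | None = None
) -> None:
    panel_to_frame(panel, freq).to_csv(path, sep="\t", index=False)
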