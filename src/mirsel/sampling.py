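"""Stratified train/test splitting and per-subtype bootstrap resampling.

The split draws round-half-up(train_frac × n) samples per subtype without
replacement — at the study's subtype sizes (86, 39, 24, 41, 41) and 80% this
yields the canonical (69, 31, 19, 33, 33) training counts, 185 train / 46
test.  Bootstrap resampling is performed within each subtype's training block
so every resample keeps the stratum proportions of the training set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class StratificationError(ValueError):
    """A subtype is too small to split."""


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 rounding up (68.8→69, 32.8→33)."""
    return int(math.floor(x + 0.5))


def derived_seed(master_seed: int, *key: int) -> int:
    """Replicate-scoped integer seed from a master seed and a key path.

    Uses a splittable counter (``numpy.random.SeedSequence``) so replicate m
    of a run is reproducible in isolation; the result fits in 31 bits.
    """
    ss = np.random.SeedSequence([int(master_seed), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SplitResult:
    """A stratified partition of sample indices into train and test."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    per_subtype_train_counts: dict[int, int]

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        overlap = np.intersect1d(self.train_indices, self.test_indices)
        if overlap.size:
            raise StratificationError("train and test indices overlap")

    @property
    def n_train(self) -> int:
        return self.train_indices.size

    @property
    def n_test(self) -> int:
        return self.test_indices.size

    def to_frame(self):
        """Index/partition table (for TSV export and split audits)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "index": np.concatenate([self.train_indices, self.test_indices]),
                "partition": ["train"] * self.n_train + ["test"] * self.n_test,
            }
        )


def stratified_split(
    labels: np.ndarray, train_frac: float = 0.8, seed: int = 0
) -> SplitResult:
    """Per-subtype random split: round-half-up(train_frac × n_subtype) to train.

    Deterministic given ``seed``; every subtype must have at least 2 samples.
    """
    labels = np.asarray(labels, dtype=int)
    if not 0.0 < train_frac < 1.0:
        raise StratificationError(f"train_frac must be in (0, 1), got {train_frac}")
    rng = np.random.default_rng(seed)
    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    counts: dict[int, int] = {}
    for code in np.unique(labels):
        idx = np.flatnonzero(labels == code)
        if idx.size < 2:
            raise StratificationError(
                f"subtype {code} has {idx.size} sample(s); at least 2 required"
            )
        n_train = round_half_up(train_frac * idx.size)
        n_train = min(max(n_train, 1), idx.size - 1)  # keep both sides non-empty
        perm = rng.permutation(idx)
        train.append(np.sort(perm[:n_train]))
        test.append(np.sort(perm[n_train:]))
        counts[int(code)] = n_train
    return SplitResult(
        train_indices=np.concatenate(train),
        test_indices=np.concatenate(test),
        seed=int(seed),
        per_subtype_train_counts=counts,
    )


def bootstrap_per_subtype(
    split: SplitResult, labels: np.ndarray, seed: int
) -> np.ndarray:
    """With-replacement resample of the training set, drawn within each subtype.

    For each subtype independently, draws a resample of size equal to that
    subtype's training count from that subtype's training indices only, then
    concatenates.  Deterministic given ``seed``.
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    blocks = []
    for code in sorted(split.per_subtype_train_counts):
        members = split.train_indices[labels[split.train_indices] == code]
        blocks.append(rng.choice(members, size=members.size, replace=True))
    return np.concatenate(blocks)
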