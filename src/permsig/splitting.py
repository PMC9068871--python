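"""Seed-driven balanced sample division and within-training resampling.

Both operations stratify by class: each class is permuted independently and
``floor(fraction * class_size)`` samples go to the training (or fit) side,
the remainder to the test (or evaluation) side.  The floor rule keeps the
training side no larger than requested when class sizes are odd.  All
randomness flows from integer seeds through ``numpy.random.SeedSequence`` so
identical inputs give identical partitions across runs, platforms and
degrees of parallelism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import LabeledDataset
from .errors import InputError

__all__ = ["SplitPlan", "rng_from", "derive_seed", "balanced_split", "balanced_resample"]

SeedLike = int | tuple


def rng_from(seed: SeedLike) -> np.random.Generator:
    """Deterministic generator from an integer seed or a tuple of integers.

    Tuples let a single root seed drive independent, reproducible substreams
    (one per division, round, or purpose) without seed collisions.
    """
    entropy = seed if isinstance(seed, tuple) else (int(seed),)
    return np.random.default_rng(np.random.SeedSequence(tuple(int(k) for k in entropy)))


def derive_seed(root_seed: int, *keys: int) -> int:
    """Mix ``keys`` (round index, purpose tag, ...) into ``root_seed``.

    Returns a non-negative integer below 2**31, suitable as a scikit-learn
    ``random_state``.
    """
    ss = np.random.SeedSequence(tuple(int(k) for k in (root_seed, *keys)))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class SplitPlan:
    """A reusable train/test membership, serialisable to TSV."""

    train_ids: list[str]
    test_ids: list[str]
    seed: SeedLike

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        frame = pd.DataFrame(
            {
                "sample_id": self.train_ids + self.test_ids,
                "partition": ["train"] * len(self.train_ids)
                + ["test"] * len(self.test_ids),
            }
        )
        frame.to_csv(path, sep=delimiter, index=False)

    @classmethod
    def read(cls, path: str | Path, delimiter: str = "\t") -> "SplitPlan":
        frame = pd.read_csv(path, sep=delimiter, dtype=str)
        train = frame.loc[frame["partition"] == "train", "sample_id"].tolist()
        test = frame.loc[frame["partition"] == "test", "sample_id"].tolist()
        return cls(train_ids=train, test_ids=test, seed=-1)


def _stratified_indices(
    data: LabeledDataset, fraction: float, seed: SeedLike, what: str
) -> tuple[list[int], list[int]]:
    if data.labels is None:
        raise InputError("labels required for balanced splitting")
    if not 0.0 < fraction < 1.0:
        raise InputError(f"fraction must lie in (0, 1), got {fraction}")
    rng = rng_from(seed)
    labels = np.asarray(data.labels, dtype=str)
    first: list[int] = []
    second: list[int] = []
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise InputError(f"class {cls!r} has fewer than 2 samples")
        n_first = int(np.floor(fraction * len(idx)))
        if n_first == 0 or n_first == len(idx):
            raise InputError(
                f"fraction {fraction} leaves class {cls!r} empty on one {what} side"
            )
        perm = rng.permutation(idx)
        first.extend(perm[:n_first].tolist())
        second.extend(perm[n_first:].tolist())
    return sorted(first), sorted(second)


def balanced_split(data: LabeledDataset, fraction: float = 0.5, seed: SeedLike = 0) -> SplitPlan:
    """Stratified train/test division: per class, ``floor(fraction * n)`` to
    train, the remainder to test."""
    train_idx, test_idx = _stratified_indices(data, fraction, seed, "split")
    return SplitPlan(
        train_ids=[data.sample_ids[i] for i in train_idx],
        test_ids=[data.sample_ids[i] for i in test_idx],
        seed=seed,
    )


def balanced_resample(
    train: LabeledDataset, fraction: float = 0.7, seed: SeedLike = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Per-class fit/evaluation partition of a training set (no replacement).

    Returns ``(fit_part, eval_part)``; their union is ``train`` and they are
    disjoint.
    """
    fit_idx, eval_idx = _stratified_indices(train, fraction, seed, "resample")
    fit = train.subset_samples([train.sample_ids[i] for i in fit_idx])
    evl = train.subset_samples([train.sample_ids[i] for i in eval_idx])
    return fit, evl
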