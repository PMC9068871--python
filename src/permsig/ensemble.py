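"""Ensemble classification over a fixed feature subset.

An :class:`EnsembleModel` is a bag of best-of-pool base classifiers, one per
resampling round: each round draws a balanced 70/30 fit/evaluation partition
of the training set (restricted to the chosen features), trains the
seven-member pool, and keeps the member with the lowest balanced error.  Test
samples are classified by unweighted majority vote; the vote fraction (share
of members voting positive) doubles as the continuous score behind ROC
curves.

Building ensembles over successive prefixes of a score ranking
(:func:`incremental_dimensions`) shows how performance grows as features are
added in descending accumulated-score order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import LabeledDataset
from .errors import InputError
from .scoring import ClassifierPool, pool_for, train_pool_and_pick
from .splitting import balanced_resample, derive_seed

__all__ = [
    "EnsembleModel",
    "build_ensemble",
    "vote_scores",
    "classify",
    "incremental_dimensions",
]


@dataclass
class EnsembleModel:
    """Bag of trained base classifiers over one feature subset."""

    feature_ids: list[str]
    members: list[tuple[str, object]]  # (pool member name, fitted estimator)
    member_errors: list[float]
    n_rounds: int
    root_seed: int
    positive_label: str
    negative_label: str

    @property
    def member_names(self) -> list[str]:
        return [name for name, _ in self.members]

    def manifest_lines(self) -> list[str]:
        """Text description sufficient to rebuild the ensemble."""
        lines = [
            f"n_rounds\t{self.n_rounds}",
            f"root_seed\t{self.root_seed}",
            f"positive_label\t{self.positive_label}",
            "features\t" + ",".join(self.feature_ids),
        ]
        lines += [
            f"member\t{j}\t{name}\t{err:.10g}"
            for j, ((name, _), err) in enumerate(zip(self.members, self.member_errors))
        ]
        return lines

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.manifest_lines()) + "\n")


def build_ensemble(
    train: LabeledDataset,
    feature_ids: Sequence[str],
    n_rounds: int,
    pool: ClassifierPool | None = None,
    root_seed: int = 0,
    resample_fraction: float = 0.7,
) -> EnsembleModel:
    """One best-of-pool member per balanced resampling round.

    Every member is trained only on ``feature_ids``; members are kept
    regardless of their evaluation error (no filtering).  Deterministic for a
    given ``root_seed``.
    """
    if not feature_ids:
        raise InputError("feature subset must be non-empty")
    sub = train.subset_features(list(feature_ids))
    if pool is None:
        pool = pool_for(sub)
    if n_rounds < 1:
        raise InputError("n_rounds must be >= 1")
    members: list[tuple[str, object]] = []
    errors: list[float] = []
    for j in range(n_rounds):
        fit_part, eval_part = balanced_resample(
            sub, resample_fraction, seed=(root_seed, j, 11)
        )
        name, clf, err = train_pool_and_pick(
            fit_part, eval_part, pool, seed=derive_seed(root_seed, j, 12)
        )
        members.append((name, clf))
        errors.append(err)
    return EnsembleModel(
        feature_ids=list(feature_ids),
        members=members,
        member_errors=errors,
        n_rounds=n_rounds,
        root_seed=root_seed,
        positive_label=str(train.positive_label),
        negative_label=train.negative_label,
    )


def vote_scores(model: EnsembleModel, samples: LabeledDataset) -> np.ndarray:
    """Fraction of members voting positive, per sample; in [0, 1]."""
    missing = [f for f in model.feature_ids if f not in samples.feature_ids]
    if missing:
        raise InputError(f"samples lack required features: {missing}")
    X = samples.subset_features(model.feature_ids).matrix
    votes = np.zeros(len(X))
    for _, clf in model.members:
        votes += np.asarray(clf.predict(X)) == 1
    return votes / len(model.members)


def classify(
    model: EnsembleModel,
    samples: LabeledDataset,
    vote_threshold: float = 0.5,
) -> np.ndarray:
    """Majority-vote labels: positive iff the vote fraction exceeds
    ``vote_threshold``; an exact 50/50 tie at the default threshold goes to
    the positive class."""
    scores = vote_scores(model, samples)
    positive = scores > vote_threshold
    if vote_threshold == 0.5:
        positive |= scores == 0.5
    return np.where(positive, model.positive_label, model.negative_label).astype(object)


def incremental_dimensions(
    train: LabeledDataset,
    ranked_features: Sequence[str],
    n_rounds: int,
    pool: ClassifierPool | None = None,
    root_seed: int = 0,
    resample_fraction: float = 0.7,
) -> list[EnsembleModel]:
    """Ensembles over every prefix of ``ranked_features`` (dims 1..K).

    Each prefix uses the same ``root_seed``, so the size-K model is exactly
    ``build_ensemble`` on the full ranking.
    """
    if not ranked_features:
        raise InputError("ranked_features must be non-empty")
    return [
        build_ensemble(
            train,
            list(ranked_features[:k]),
            n_rounds,
            pool=pool,
            root_seed=root_seed,
            resample_fraction=resample_fraction,
        )
        for k in range(1, len(ranked_features) + 1)
    ]
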