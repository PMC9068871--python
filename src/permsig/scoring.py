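"""Resample–train–score engine producing accumulated permutation importances.

Each round ``j`` draws a balanced 70/30 fit/evaluation partition of the
training set, trains a pool of seven base classifiers (decision tree,
multinomial naive Bayes, k-nearest-neighbour, linear discriminant, logistic
regression, multi-layer perceptron, linear support-vector machine) on the fit
part using *all* features, and keeps the member with the lowest balanced
error rate on the evaluation part

    Err = (FN/(TP+FN) + FP/(TN+FP)) / 2 .

For every feature ``i`` the evaluation column is then randomly permuted
(breaking any feature/label association while preserving the marginal
distribution) and the winner — *not* retrained — is re-evaluated, giving the
round score

    score_j^i = Err~ - Err ,

the increase in balanced error caused by scrambling feature ``i``.  The
accumulated score of a feature is the mean of its round scores over ``N``
rounds.  Features irrelevant to the winner score ~0; features the winner
leans on score positive.

Rounds are mutually independent and keyed by ``(root_seed, round_index)``, so
serial and parallel execution produce bit-identical results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data import LabeledDataset, ScoreTable
from .errors import InputError, NumericalError
from .splitting import SeedLike, balanced_resample, derive_seed, rng_from

__all__ = [
    "POOL_ORDER",
    "ClassifierPool",
    "default_pool",
    "RoundRecord",
    "AccumulatedScores",
    "balanced_error",
    "confusion_counts",
    "train_pool_and_pick",
    "permutation_score",
    "run_scoring",
]

log = logging.getLogger(__name__)

#: Fixed pool order; also the tie-breaking order when two members reach the
#: same balanced error.
POOL_ORDER = ("DTC", "MNB", "KNN", "LDA", "LR", "MLP", "SVM")

#: Default hyperparameters; every entry can be overridden via
#: ``default_pool(hyperparameters=...)``.  Sizes are kept modest because each
#: member is refitted tens of thousands of times.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "DTC": {},
    "MNB": {"alpha": 1.0},
    "KNN": {"n_neighbors": 5},
    "LDA": {"solver": "svd"},
    "LR": {"solver": "lbfgs", "max_iter": 200},
    "MLP": {"hidden_layer_sizes": (16,), "solver": "lbfgs", "max_iter": 150},
    "SVM": {"kernel": "linear", "C": 1.0},
}


def _factories(hp: dict[str, dict]) -> dict[str, Callable[[int], object]]:
    return {
        "DTC": lambda s: DecisionTreeClassifier(random_state=s, **hp["DTC"]),
        "MNB": lambda s: MultinomialNB(**hp["MNB"]),
        "KNN": lambda s: KNeighborsClassifier(**hp["KNN"]),
        "LDA": lambda s: LinearDiscriminantAnalysis(**hp["LDA"]),
        "LR": lambda s: LogisticRegression(random_state=s, **hp["LR"]),
        "MLP": lambda s: MLPClassifier(random_state=s, **hp["MLP"]),
        "SVM": lambda s: SVC(random_state=s, **hp["SVM"]),
    }


@dataclass
class ClassifierPool:
    """Ordered pool of base-classifier specifications.

    ``members`` maps name -> factory(seed) -> unfitted estimator; the mapping
    preserves :data:`POOL_ORDER` (used for tie-breaking).
    """

    members: dict[str, Callable[[int], object]]

    def __post_init__(self) -> None:
        if not self.members:
            raise InputError("classifier pool is empty")

    @property
    def names(self) -> list[str]:
        return list(self.members)

    def make(self, name: str, seed: int) -> object:
        return self.members[name](seed)


def default_pool(
    hyperparameters: dict[str, dict] | None = None,
    exclude: Sequence[str] = (),
) -> ClassifierPool:
    """The seven-member pool in its canonical order.

    ``hyperparameters`` entries are merged over the defaults per member;
    ``exclude`` drops members by name (e.g. ``("MNB",)`` for data with
    negative values, which multinomial naive Bayes cannot accept).
    """
    hp = {k: dict(v) for k, v in DEFAULT_HYPERPARAMETERS.items()}
    for name, over in (hyperparameters or {}).items():
        if name not in hp:
            raise InputError(f"unknown pool member {name!r}")
        hp[name].update(over)
    factories = _factories(hp)
    members = {n: factories[n] for n in POOL_ORDER if n not in set(exclude)}
    return ClassifierPool(members=members)


def pool_for(data: LabeledDataset, hyperparameters: dict[str, dict] | None = None) -> ClassifierPool:
    """Default pool, auto-skipping multinomial naive Bayes when the matrix
    contains negative values (logged)."""
    exclude: tuple[str, ...] = ()
    if (data.matrix < 0).any():
        log.warning("matrix has negative values; skipping MNB pool member")
        exclude = ("MNB",)
    return default_pool(hyperparameters=hyperparameters, exclude=exclude)


# ---------------------------------------------------------------------------
# balanced error


def balanced_error(tp: int, fn: int, tn: int, fp: int) -> float:
    """Mean of the two class-conditional error rates; in [0, 1].

    Insensitive to class imbalance: it equals the plain error rate only when
    the classes are balanced.
    """
    if min(tp, fn, tn, fp) < 0:
        raise InputError("confusion counts must be non-negative")
    if tp + fn < 1 or tn + fp < 1:
        raise InputError("balanced error undefined for an empty class")
    return (fn / (tp + fn) + fp / (tn + fp)) / 2.0


def confusion_counts(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[int, int, int, int]:
    """(tp, fn, tn, fp) from boolean is-positive vectors."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    tp = int(np.sum(y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fp = int(np.sum(~y_true & y_pred))
    return tp, fn, tn, fp


def _eval_balanced_error(clf, X: np.ndarray, y_pos: np.ndarray) -> float:
    pred = np.asarray(clf.predict(X))
    tp, fn, tn, fp = confusion_counts(y_pos, pred == 1)
    return balanced_error(tp, fn, tn, fp)


# ---------------------------------------------------------------------------
# round records


@dataclass
class RoundRecord:
    """One iteration: the winning member, its balanced error on the
    evaluation part, and the per-feature permutation scores."""

    round_index: int
    winner: str
    base_error: float
    per_feature_scores: np.ndarray


@dataclass
class AccumulatedScores:
    """Mean per-feature permutation score over ``n_rounds`` rounds, plus the
    winner tally backing the classifier-contribution pie chart."""

    feature_ids: list[str]
    per_feature: np.ndarray
    per_feature_sq_mean: np.ndarray
    n_rounds: int
    winner_tally: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.per_feature) != len(self.feature_ids):
            raise InputError("one accumulated score per feature required")
        if sum(self.winner_tally.values()) != self.n_rounds:
            raise InputError("winner tally must sum to n_rounds")

    def monte_carlo_sem(self) -> np.ndarray:
        """Per-feature standard error of the accumulated-score mean."""
        var = np.maximum(self.per_feature_sq_mean - self.per_feature**2, 0.0)
        return np.sqrt(var / max(self.n_rounds, 1))

    def to_score_table(self) -> ScoreTable:
        return ScoreTable(
            feature_ids=list(self.feature_ids),
            accumulated_scores=self.per_feature.copy(),
            n_rounds=self.n_rounds,
        )

    def winner_tally_frame(self) -> pd.DataFrame:
        rows = [
            (name, count, count / self.n_rounds)
            for name, count in sorted(self.winner_tally.items())
        ]
        return pd.DataFrame(rows, columns=["classifier", "count", "fraction"])


# ---------------------------------------------------------------------------
# training + picking


def train_pool_and_pick(
    fit_part: LabeledDataset,
    eval_part: LabeledDataset,
    pool: ClassifierPool,
    seed: int = 0,
) -> tuple[str, object, float]:
    """Fit every pool member on ``fit_part`` (all features), evaluate each on
    ``eval_part`` by balanced error, and return the winner.

    Ties go to the earlier pool member.  Members that raise during fit are
    skipped with a logged warning; an empty surviving pool is an error.
    Returns ``(name, fitted_estimator, base_error)``.
    """
    X_fit = fit_part.matrix
    y_fit = fit_part.y_binary().astype(int)
    X_eval = eval_part.matrix
    y_eval = eval_part.y_binary()
    if y_fit.min() == y_fit.max() or y_eval.min() == y_eval.max():
        raise InputError("both partitions must contain both classes")

    best: tuple[float, int, str, object] | None = None
    for order, name in enumerate(pool.names):
        clf = pool.make(name, derive_seed(seed, order))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(X_fit, y_fit)
            err = _eval_balanced_error(clf, X_eval, y_eval)
        except Exception as exc:  # noqa: BLE001 - member skip is the contract
            log.warning("pool member %s failed and was skipped: %s", name, exc)
            continue
        if best is None or err < best[0]:
            best = (err, order, name, clf)
    if best is None:
        raise NumericalError("every pool member failed to train")
    err, _, name, clf = best
    return name, clf, err


# ---------------------------------------------------------------------------
# permutation scoring


def permutation_score(
    winner,
    eval_part: LabeledDataset,
    feature_index: int,
    base_error: float,
    rng: np.random.Generator,
) -> float:
    """Err~ - Err for one feature: permute its evaluation column, re-evaluate
    the already-fitted winner, and report the error increase.

    ``eval_part`` is not modified.  A constant column is unaffected by
    permutation in distribution but still consumes one draw from ``rng`` so
    scores are reproducible regardless of which features are constant.
    """
    n, p = eval_part.matrix.shape
    if not 0 <= feature_index < p:
        raise InputError(f"feature index {feature_index} out of range [0, {p})")
    perm = rng.permutation(n)
    X = eval_part.matrix.copy()
    X[:, feature_index] = X[perm, feature_index]
    err_perm = _eval_balanced_error(winner, X, eval_part.y_binary())
    return err_perm - base_error


def _all_permutation_scores(
    winner,
    eval_part: LabeledDataset,
    base_error: float,
    rng: np.random.Generator,
    chunk: int = 64,
) -> np.ndarray:
    """Vectorised equivalent of calling :func:`permutation_score` for every
    feature in index order with the same ``rng``.

    Features are processed in blocks: the evaluation matrix is tiled, each
    copy gets one permuted column, and a single ``predict`` call covers the
    whole block.  Identical draws, identical results, far fewer predict calls.
    """
    X = eval_part.matrix
    y = eval_part.y_binary()
    n, p = X.shape
    pos, neg = int(y.sum()), int((~y).sum())
    scores = np.empty(p, dtype=float)
    for start in range(0, p, chunk):
        stop = min(start + chunk, p)
        m = stop - start
        block = np.broadcast_to(X, (m, n, p)).copy()
        for k, j in enumerate(range(start, stop)):
            perm = rng.permutation(n)
            block[k, :, j] = X[perm, j]
        pred = np.asarray(winner.predict(block.reshape(m * n, p))).reshape(m, n) == 1
        fn = np.sum(y & ~pred, axis=1)
        fp = np.sum(~y & pred, axis=1)
        scores[start:stop] = (fn / pos + fp / neg) / 2.0 - base_error
    return scores


# ---------------------------------------------------------------------------
# the full loop


def _run_round(
    train: LabeledDataset,
    j: int,
    pool: ClassifierPool,
    resample_fraction: float,
    root_seed: int,
    chunk: int,
) -> RoundRecord:
    fit_part, eval_part = balanced_resample(
        train, resample_fraction, seed=(root_seed, j, 1)
    )
    name, clf, err = train_pool_and_pick(
        fit_part, eval_part, pool, seed=derive_seed(root_seed, j, 2)
    )
    rng = rng_from((root_seed, j, 3))
    scores = _all_permutation_scores(clf, eval_part, err, rng, chunk=chunk)
    return RoundRecord(round_index=j, winner=name, base_error=err, per_feature_scores=scores)


def run_scoring(
    train: LabeledDataset,
    n_rounds: int,
    pool: ClassifierPool | None = None,
    resample_fraction: float = 0.7,
    root_seed: int = 0,
    n_jobs: int = 1,
    chunk: int = 64,
    progress_every: int = 0,
) -> AccumulatedScores:
    """Run ``n_rounds`` independent resample–train–score rounds and average.

    Deterministic given ``root_seed``; ``n_jobs`` distributes rounds without
    changing any result (each round owns its seed substream, and partial sums
    are combined in round order).
    """
    if n_rounds < 1:
        raise InputError("n_rounds must be >= 1")
    if pool is None:
        pool = pool_for(train)

    acc = np.zeros(train.n_features)
    acc_sq = np.zeros(train.n_features)
    tally: dict[str, int] = {}

    def consume(rec: RoundRecord) -> None:
        np.add(acc, rec.per_feature_scores, out=acc)
        np.add(acc_sq, rec.per_feature_scores**2, out=acc_sq)
        tally[rec.winner] = tally.get(rec.winner, 0) + 1
        if progress_every and (rec.round_index + 1) % progress_every == 0:
            log.info(
                "round %d/%d winner=%s err=%.4f",
                rec.round_index + 1,
                n_rounds,
                rec.winner,
                rec.base_error,
            )

    if n_jobs == 1:
        for j in range(n_rounds):
            consume(_run_round(train, j, pool, resample_fraction, root_seed, chunk))
    else:
        records = Parallel(n_jobs=n_jobs, return_as="generator")(
            delayed(_run_round)(train, j, pool, resample_fraction, root_seed, chunk)
            for j in range(n_rounds)
        )
        for rec in records:  # joblib preserves submission order
            consume(rec)

    return AccumulatedScores(
        feature_ids=list(train.feature_ids),
        per_feature=acc / n_rounds,
        per_feature_sq_mean=acc_sq / n_rounds,
        n_rounds=n_rounds,
        winner_tally=tally,
    )
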