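"""Dataset model and delimited-text I/O.

The universal input is a :class:`LabeledDataset`: a dense ``n_samples x
n_features`` expression matrix with unique string identifiers on both axes and
a binary class label per sample (positive = tumor/case, negative =
normal/control by convention).  Matrices travel as plain TSV/CSV with one
header row and one identifier column; on-disk orientation (features in rows,
the common export convention, or features in columns) is normalised away at
load time so the in-memory matrix is always samples x features.

Loading is strict: ragged rows, non-numeric cells, missing values and
duplicate identifiers are rejected with messages naming the offending
line/cell rather than silently imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "LabeledDataset",
    "ScoreTable",
    "load_expression_matrix",
    "load_labels",
    "attach_labels",
    "filter_zero_variance",
    "write_expression_matrix",
    "write_labels",
    "write_score_table",
    "read_score_table",
]

#: float format used for every TSV we write; 17 significant digits make the
#: write -> load round trip lossless for float64.
FLOAT_FORMAT = "%.17g"

ORIENTATIONS = ("features-in-rows", "features-in-columns")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dupes = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise InputError(f"duplicate {what} ids: {', '.join(map(str, dupes))}")


@dataclass
class LabeledDataset:
    """Expression matrix plus identifiers and (optionally) binary labels.

    Attributes
    ----------
    matrix:
        ``(n_samples, n_features)`` float array, no missing values.
    feature_ids, sample_ids:
        Unique identifier strings for columns / rows of ``matrix``.
    labels:
        Per-sample class labels aligned with ``sample_ids``; ``None`` until
        :func:`attach_labels` is called.
    positive_label:
        Which of the two classes is the positive (case/tumor) class.
    """

    matrix: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray | None = None
    positive_label: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise InputError("matrix must be two-dimensional")
        n, p = self.matrix.shape
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise InputError(
                f"id/matrix shape mismatch: matrix {n}x{p}, "
                f"{len(self.sample_ids)} sample ids, {len(self.feature_ids)} feature ids"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.matrix).all():
            bad = np.argwhere(~np.isfinite(self.matrix))[0]
            raise InputError(
                "matrix contains missing/non-finite values, e.g. at "
                f"sample {self.sample_ids[bad[0]]!r}, feature {self.feature_ids[bad[1]]!r}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (n,):
                raise InputError("labels must align with sample_ids")
            if len(set(map(str, self.labels))) > 2:
                raise InputError(
                    f"expected at most two classes, got {sorted(set(map(str, self.labels)))}"
                )

    def validate_two_classes(self) -> None:
        """Full-dataset invariant: exactly two classes, each with >= 2
        samples.  Enforced at label attachment; partition subsets (e.g. a
        one-negative evaluation part) are exempt."""
        classes, counts = np.unique(np.asarray(self.labels, dtype=str), return_counts=True)
        if len(classes) != 2:
            raise InputError(
                f"expected exactly two classes, got {len(classes)}: {list(classes)}"
            )
        small = [str(c) for c, k in zip(classes, counts) if k < 2]
        if small:
            raise InputError(f"classes with fewer than 2 samples: {small}")
        if self.positive_label is not None and str(self.positive_label) not in classes:
            raise InputError(
                f"positive_label {self.positive_label!r} not among classes {list(classes)}"
            )

    # -- basic views ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> list[str]:
        if self.labels is None:
            raise InputError("dataset has no labels attached")
        return sorted(set(map(str, self.labels)))

    @property
    def negative_label(self) -> str:
        pos = self.positive_label
        return next(c for c in self.classes if c != pos)

    def class_counts(self) -> dict[str, int]:
        classes, counts = np.unique(np.asarray(self.labels, dtype=str), return_counts=True)
        return dict(zip(classes.tolist(), counts.tolist()))

    def y_binary(self) -> np.ndarray:
        """Boolean vector, True where the sample is positive."""
        if self.labels is None or self.positive_label is None:
            raise InputError("dataset has no labels/positive class")
        return np.asarray([str(l) == str(self.positive_label) for l in self.labels])

    # -- subsetting -------------------------------------------------------

    def subset_samples(self, ids: Sequence[str]) -> "LabeledDataset":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise InputError(f"unknown sample ids: {missing}")
        rows = [index[s] for s in ids]
        return LabeledDataset(
            matrix=self.matrix[rows],
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in rows],
            labels=None if self.labels is None else self.labels[rows],
            positive_label=self.positive_label,
        )

    def subset_features(self, ids: Sequence[str]) -> "LabeledDataset":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in index]
        if missing:
            raise InputError(f"unknown feature ids: {missing}")
        cols = [index[f] for f in ids]
        return replace(
            self,
            matrix=self.matrix[:, cols],
            feature_ids=[self.feature_ids[i] for i in cols],
            labels=self.labels,
        )


@dataclass
class ScoreTable:
    """Accumulated permutation scores, one per feature."""

    feature_ids: list[str]
    accumulated_scores: np.ndarray
    n_rounds: int

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.accumulated_scores = np.asarray(self.accumulated_scores, dtype=float)
        if self.accumulated_scores.shape != (len(self.feature_ids),):
            raise InputError("one score per feature id required")
        _check_unique(self.feature_ids, "feature")
        if not np.isfinite(self.accumulated_scores).all():
            raise InputError("scores must be finite")
        if self.n_rounds < 1:
            raise InputError("n_rounds must be positive")

    def ranking(self) -> list[str]:
        """Feature ids by descending score; ties broken lexicographically."""
        order = sorted(
            range(len(self.feature_ids)),
            key=lambda i: (-self.accumulated_scores[i], self.feature_ids[i]),
        )
        return [self.feature_ids[i] for i in order]

    def as_frame(self) -> pd.DataFrame:
        rank_of = {f: r + 1 for r, f in enumerate(self.ranking())}
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "acc_score": self.accumulated_scores,
                "rank": [rank_of[f] for f in self.feature_ids],
            }
        )


# ---------------------------------------------------------------------------
# loading


def _read_delimited(path: str | Path, delimiter: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, sep=delimiter, header=0, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise InputError(f"ragged/malformed delimited file {path}: {exc}") from exc
    if frame.index.hasnans or any(c is None for c in frame.columns):
        raise InputError(f"{path}: empty identifier in header or id column")
    return frame


def _to_numeric(frame: pd.DataFrame, path: str | Path) -> np.ndarray:
    # python float() parsing is correctly rounded, making write -> load
    # round trips bit-exact (pandas' fast csv float parser is not)
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        raw = frame[col]
        if raw.isna().any():
            row = frame.index[np.argmax(raw.isna().to_numpy())]
            raise InputError(f"{path}: missing value at row {row!r}, column {col!r}")
        try:
            values[:, j] = [float(v) for v in raw.to_numpy()]
        except ValueError:
            bad = pd.to_numeric(raw, errors="coerce").isna()
            row = frame.index[np.argmax(bad.to_numpy())]
            raise InputError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
                f"{raw[bad].iloc[0]!r}"
            ) from None
    return values


def load_expression_matrix(
    path: str | Path,
    orientation: str = "features-in-rows",
    delimiter: str = "\t",
    log2_transform: bool = False,
) -> LabeledDataset:
    """Read a delimited expression matrix into a (yet unlabeled) dataset.

    ``orientation`` states how the file on disk is laid out; the returned
    matrix is always samples x features.  With ``log2_transform`` the values
    are mapped through ``log2(x + 1)`` (off by default: values pass through
    unchanged).
    """
    if orientation not in ORIENTATIONS:
        raise InputError(f"orientation must be one of {ORIENTATIONS}")
    frame = _read_delimited(path, delimiter)
    values = _to_numeric(frame, path)
    row_ids = [str(i) for i in frame.index]
    col_ids = [str(c) for c in frame.columns]
    if orientation == "features-in-rows":
        matrix, feature_ids, sample_ids = values.T, row_ids, col_ids
    else:
        matrix, feature_ids, sample_ids = values, col_ids, row_ids
    if log2_transform:
        if (matrix < 0).any():
            raise InputError("log2 transform requires non-negative values")
        matrix = np.log2(matrix + 1.0)
    return LabeledDataset(matrix=matrix, feature_ids=feature_ids, sample_ids=sample_ids)


def load_labels(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column (sample_id, label) table into a mapping."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    frame = pd.read_csv(path, sep=delimiter, header=0, dtype=str)
    if frame.shape[1] < 2:
        raise InputError(f"{path}: label table needs (sample_id, label) columns")
    ids = frame.iloc[:, 0].tolist()
    _check_unique(ids, "sample")
    return dict(zip(ids, frame.iloc[:, 1].tolist()))


def attach_labels(
    data: LabeledDataset,
    labels: Mapping[str, str],
    positive_label: str | None = None,
) -> LabeledDataset:
    """Align labels to the dataset by sample id (file order is irrelevant).

    If ``positive_label`` is omitted the lexicographically larger class name
    is taken as positive — which matches the common tumor/normal and
    case/control naming conventions; pass it explicitly otherwise.
    """
    missing = [s for s in data.sample_ids if s not in labels]
    if missing:
        raise InputError(f"unlabeled samples: {missing}")
    aligned = np.asarray([str(labels[s]) for s in data.sample_ids], dtype=object)
    classes = sorted(set(aligned))
    if len(classes) != 2:
        raise InputError(f"expected exactly two classes, got {classes}")
    if positive_label is None:
        positive_label = classes[-1]
    labeled = replace(data, labels=aligned, positive_label=str(positive_label))
    labeled.validate_two_classes()
    return labeled


def filter_zero_variance(
    data: LabeledDataset, epsilon: float = 0.0
) -> tuple[LabeledDataset, list[str]]:
    """Drop features that are constant across all samples.

    Zero variance means ``max == min`` exactly by default; ``epsilon`` widens
    the definition to ``max - min <= epsilon`` for near-constant features.
    Retained feature order is preserved.  Idempotent.
    """
    spread = data.matrix.max(axis=0) - data.matrix.min(axis=0)
    keep = spread > epsilon
    removed = [f for f, k in zip(data.feature_ids, keep) if not k]
    if not keep.any():
        raise InputError("all features have zero variance; nothing to select from")
    kept = [f for f, k in zip(data.feature_ids, keep) if k]
    return data.subset_features(kept), removed


# ---------------------------------------------------------------------------
# writing


def write_expression_matrix(
    data: LabeledDataset,
    path: str | Path,
    orientation: str = "features-in-rows",
    delimiter: str = "\t",
) -> None:
    if orientation not in ORIENTATIONS:
        raise InputError(f"orientation must be one of {ORIENTATIONS}")
    if orientation == "features-in-rows":
        frame = pd.DataFrame(
            data.matrix.T, index=data.feature_ids, columns=data.sample_ids
        )
        frame.index.name = "feature_id"
    else:
        frame = pd.DataFrame(
            data.matrix, index=data.sample_ids, columns=data.feature_ids
        )
        frame.index.name = "sample_id"
    frame.to_csv(path, sep=delimiter, float_format=FLOAT_FORMAT)


def write_labels(data: LabeledDataset, path: str | Path, delimiter: str = "\t") -> None:
    if data.labels is None:
        raise InputError("dataset has no labels to write")
    frame = pd.DataFrame({"sample_id": data.sample_ids, "label": data.labels})
    frame.to_csv(path, sep=delimiter, index=False)


def write_score_table(table: ScoreTable, path: str | Path, delimiter: str = "\t") -> None:
    table.as_frame().to_csv(path, sep=delimiter, index=False, float_format=FLOAT_FORMAT)


def read_score_table(
    path: str | Path, n_rounds: int = 1, delimiter: str = "\t"
) -> ScoreTable:
    frame = pd.read_csv(path, sep=delimiter)
    return ScoreTable(
        feature_ids=frame["feature_id"].astype(str).tolist(),
        accumulated_scores=frame["acc_score"].to_numpy(dtype=float),
        n_rounds=n_rounds,
    )
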