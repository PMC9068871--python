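"""Repeated-division stability layer and signature extraction.

A single train/test division gives one selection; how much of it is luck of
the split?  This layer repeats the whole division -> scoring -> GMM-selection
pipeline ``R`` times with independent seeds, intersects the per-division
selections into a *core* set, builds the division x feature rank matrix, and
extracts the top-``k`` signature: core features whose median rank across
divisions is within the first ``k``.

It also provides the exhaustive subset screen: every non-empty combination of
a small signature is turned into an ensemble on one dataset and evaluated on
another, which exposes features whose cross-platform scale shift hurts
transfer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import LabeledDataset
from .ensemble import build_ensemble, classify
from .errors import InputError
from .evaluation import MetricsReport, metrics_report
from .gmm import SelectionResult, fit_two_component_gmm, select_features, selection_threshold
from .scoring import AccumulatedScores, ClassifierPool, run_scoring
from .splitting import SplitPlan, balanced_split, derive_seed

__all__ = [
    "DivisionRun",
    "StabilityReport",
    "run_divisions",
    "intersect_selections",
    "rank_matrix",
    "signature_topk",
    "subset_combination_screen",
]

log = logging.getLogger(__name__)


@dataclass
class DivisionRun:
    """Everything one division produced: the split, the accumulated scores,
    and the thresholded selection."""

    division_index: int
    seed: int
    split: SplitPlan
    scores: AccumulatedScores
    selection: SelectionResult


@dataclass
class StabilityReport:
    """Per-division selections plus the derived core set, rank matrix and
    top-k signature."""

    divisions: list[DivisionRun]
    core_features: list[str]
    ranks: pd.DataFrame
    signature: list[str]
    k: int

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for run in self.divisions:
            run.selection.as_frame().to_csv(
                outdir / f"selection_division{run.division_index}.tsv",
                sep="\t",
                index=False,
                float_format="%.17g",
            )
        self.ranks.to_csv(outdir / "rank_matrix.tsv", sep="\t")
        pd.DataFrame({"feature_id": self.core_features}).to_csv(
            outdir / "core_features.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {"rank": range(1, len(self.signature) + 1), "feature_id": self.signature}
        ).to_csv(outdir / "signature.tsv", sep="\t", index=False)


def run_divisions(
    data: LabeledDataset,
    R: int,
    n_rounds: int,
    pool: ClassifierPool | None = None,
    split_fraction: float = 0.5,
    resample_fraction: float = 0.7,
    root_seed: int = 0,
    n_jobs: int = 1,
    threshold_override: float | None = None,
    gmm_seed: int = 0,
) -> list[DivisionRun]:
    """``R`` independent full pipeline runs (split -> scoring -> selection).

    Division ``r`` derives its seed from ``(root_seed, r)``; results are
    independent of each other and reproducible.  ``threshold_override``
    replaces the GMM common-boundary threshold with a manual cut.
    """
    if R < 1:
        raise InputError("R must be >= 1")
    runs: list[DivisionRun] = []
    for r in range(R):
        seed_r = derive_seed(root_seed, r, 21)
        split = balanced_split(data, split_fraction, seed=seed_r)
        train = data.subset_samples(split.train_ids)
        scores = run_scoring(
            train,
            n_rounds,
            pool=pool,
            resample_fraction=resample_fraction,
            root_seed=seed_r,
            n_jobs=n_jobs,
        )
        table = scores.to_score_table()
        if threshold_override is not None:
            threshold = float(threshold_override)
        else:
            fit = fit_two_component_gmm(table.accumulated_scores, seed=gmm_seed)
            threshold = selection_threshold(fit)
        selection = select_features(table, threshold)
        log.info(
            "division %d: %d features above threshold %.6g",
            r,
            len(selection.selected_feature_ids),
            threshold,
        )
        runs.append(
            DivisionRun(
                division_index=r,
                seed=seed_r,
                split=split,
                scores=scores,
                selection=selection,
            )
        )
    return runs


def _selections(results: Sequence[DivisionRun | SelectionResult]) -> list[SelectionResult]:
    return [r.selection if isinstance(r, DivisionRun) else r for r in results]


def intersect_selections(results: Sequence[DivisionRun | SelectionResult]) -> list[str]:
    """Features selected in *every* division, ordered by descending mean
    accumulated score (ties by feature id)."""
    sels = _selections(results)
    if not sels:
        raise InputError("need at least one selection result")
    core = set(sels[0].selected_feature_ids)
    for sel in sels[1:]:
        core &= set(sel.selected_feature_ids)
    if not core:
        log.warning("intersection of selections is empty")
        return []
    mean_score: dict[str, float] = {}
    for f in core:
        vals = []
        for sel in sels:
            lookup = dict(zip(sel.all_scores.feature_ids, sel.all_scores.accumulated_scores))
            vals.append(lookup[f])
        mean_score[f] = float(np.mean(vals))
    return sorted(core, key=lambda f: (-mean_score[f], f))


def rank_matrix(
    results: Sequence[DivisionRun | SelectionResult],
    core_features: Sequence[str],
) -> pd.DataFrame:
    """1-based rank of each core feature within each division's full
    selection (divisions as rows, features as columns)."""
    sels = _selections(results)
    rows = []
    for d, sel in enumerate(sels):
        position = {f: i + 1 for i, f in enumerate(sel.selected_feature_ids)}
        missing = [f for f in core_features if f not in position]
        if missing:
            raise InputError(
                f"core feature(s) {missing} not selected in division {d}; "
                "core must be the intersection"
            )
        rows.append([position[f] for f in core_features])
    frame = pd.DataFrame(rows, columns=list(core_features))
    frame.index.name = "division"
    return frame


def signature_topk(ranks: pd.DataFrame, k: int = 5) -> list[str]:
    """Core features whose median rank across divisions is <= ``k``, ordered
    by median rank, then mean rank, then feature id; truncated at ``k``."""
    if k < 1:
        raise InputError("k must be >= 1")
    med = ranks.median(axis=0)
    mean = ranks.mean(axis=0)
    qualifying = [f for f in ranks.columns if med[f] <= k]
    qualifying.sort(key=lambda f: (med[f], mean[f], f))
    if len(qualifying) < k:
        log.warning("only %d features have median rank <= %d", len(qualifying), k)
    if len(qualifying) > k:
        log.info("more than %d features qualify; truncating", k)
    return qualifying[:k]


def subset_combination_screen(
    train: LabeledDataset,
    test: LabeledDataset,
    features: Sequence[str],
    n_rounds: int,
    pool: ClassifierPool | None = None,
    root_seed: int = 0,
    max_features: int = 12,
) -> pd.DataFrame:
    """Evaluate an ensemble for every non-empty subset of ``features``.

    Each subset gets an ensemble built on ``train`` (same root seed, so
    subsets differ only in their features) and a one-vs-rest metrics report
    on ``test``.  Rows are ordered by weighted F1, best first.
    """
    features = list(features)
    if not features:
        raise InputError("feature list must be non-empty")
    if len(features) > max_features:
        raise InputError(
            f"{len(features)} features would enumerate 2^{len(features)}-1 subsets; "
            "pass an explicit subset list instead"
        )
    rows = []
    for size in range(1, len(features) + 1):
        for combo in combinations(features, size):
            model = build_ensemble(
                train, list(combo), n_rounds, pool=pool, root_seed=root_seed
            )
            predicted = classify(model, test)
            report = metrics_report(test.labels, predicted)
            rows.append(
                {
                    "subset": ",".join(combo),
                    "size": size,
                    "weighted_f1": report.weighted["f1"],
                    "weighted_tp_rate": report.weighted["tp_rate"],
                    "weighted_precision": report.weighted["precision"],
                }
            )
    frame = pd.DataFrame(rows).sort_values(
        ["weighted_f1", "size", "subset"], ascending=[False, True, True]
    )
    return frame.reset_index(drop=True)
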