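"""Two-component Gaussian-mixture thresholding of accumulated scores.

After many scoring rounds the accumulated scores of uninformative features
pile up near zero while informative features sit to the right; a
two-component Gaussian mixture fitted by EM separates the two groups.  The
selection threshold is the *common boundary* of the weighted component
densities — the point between the two means where

    w_low N(x | m_low, v_low) = w_high N(x | m_high, v_high),

equivalently the equal-posterior point.  Features scoring strictly above the
boundary are selected and ranked by accumulated score.

The EM implementation is one-dimensional and purposely transparent: it
records the log-likelihood at every iteration (non-decreasing by the EM
guarantee — asserted in tests), initialises from a seeded 2-means partition,
and aborts with a :class:`~permsig.errors.DegenerateFitError` when a
component variance collapses below the floor (typically a sign that more
scoring rounds are needed, or that a manual threshold should be supplied).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .data import ScoreTable
from .errors import DegenerateFitError, InputError
from .splitting import rng_from

__all__ = [
    "GmmFit",
    "SelectionResult",
    "fit_two_component_gmm",
    "selection_threshold",
    "select_features",
]

log = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-12


@dataclass
class GmmFit:
    """Parameters of a fitted two-component 1-D Gaussian mixture.

    Components are ordered by mean; the larger-mean component is the
    "selected" side of the score distribution.
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood_trace: list[float]
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)

    def report_lines(self) -> list[str]:
        return [
            f"weight_low\t{self.weights[0]:.10g}",
            f"weight_high\t{self.weights[1]:.10g}",
            f"mean_low\t{self.means[0]:.10g}",
            f"mean_high\t{self.means[1]:.10g}",
            f"variance_low\t{self.variances[0]:.10g}",
            f"variance_high\t{self.variances[1]:.10g}",
            f"converged\t{self.converged}",
            f"n_iter\t{self.n_iter}",
            f"log_likelihood\t{self.log_likelihood_trace[-1]:.10g}",
        ]


@dataclass
class SelectionResult:
    """Features above the threshold, ranked by accumulated score
    (descending; ties broken by feature id)."""

    threshold: float
    selected_feature_ids: list[str]
    all_scores: ScoreTable

    def as_frame(self):
        frame = self.all_scores.as_frame()
        frame["selected"] = frame["feature_id"].isin(set(self.selected_feature_ids))
        return frame.sort_values("rank").reset_index(drop=True)


def _two_means_partition(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Seeded Lloyd iteration with k=2 on the line; returns a boolean mask of
    the higher cluster.  Neither side is allowed to shrink below two points
    (a singleton cluster would hand EM a zero-variance component)."""
    uniq = np.unique(x)
    centers = np.sort(rng.choice(uniq, size=2, replace=False))
    hi = x > np.median(x)
    for _ in range(200):
        candidate = np.abs(x - centers[1]) < np.abs(x - centers[0])
        if candidate.sum() < 2 or (~candidate).sum() < 2:
            break
        hi = candidate
        new = np.array([x[~hi].mean(), x[hi].mean()])
        if np.allclose(new, centers):
            break
        centers = np.sort(new)
    if hi.sum() < 2 or (~hi).sum() < 2:
        hi = x > np.median(x)
    return hi


def _log_pdf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * math.pi * var) + (x - mean) ** 2 / var)


def fit_two_component_gmm(
    scores: np.ndarray,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> GmmFit:
    """Fit a two-component Gaussian mixture to scalar scores by EM.

    Initialisation is a seeded 2-means partition; convergence is a relative
    log-likelihood change below ``tol``.  Requires at least four distinct
    values.
    """
    x = np.asarray(scores, dtype=float).ravel()
    if not np.isfinite(x).all():
        raise InputError("scores must be finite")
    if len(np.unique(x)) < 4:
        raise DegenerateFitError(
            "need >= 4 distinct score values for a two-component fit; "
            "run more scoring rounds or pass an explicit threshold"
        )
    rng = rng_from((int(seed), 0x6D6D))
    hi = _two_means_partition(x, rng)

    weights = np.array([(~hi).mean(), hi.mean()])
    means = np.array([x[~hi].mean(), x[hi].mean()])
    variances = np.array([x[~hi].var(), x[hi].var()])
    # a tight initial cluster must not start EM on the brink of collapse
    variances = np.maximum(variances, 1e-4 * max(x.var(), 10 * VARIANCE_FLOOR))

    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E step
        log_comp = np.stack(
            [
                np.log(weights[k]) + _log_pdf(x, means[k], variances[k])
                for k in (0, 1)
            ]
        )
        log_norm = np.logaddexp(log_comp[0], log_comp[1])
        trace.append(float(log_norm.sum()))
        resp = np.exp(log_comp - log_norm)
        # M step
        nk = resp.sum(axis=1)
        if nk.min() <= 0:
            raise DegenerateFitError("a mixture component lost all responsibility")
        weights = nk / len(x)
        means = (resp @ x) / nk
        variances = np.array(
            [(resp[k] @ (x - means[k]) ** 2) / nk[k] for k in (0, 1)]
        )
        if variances.min() < VARIANCE_FLOOR:
            raise DegenerateFitError(
                "mixture variance collapsed below the floor; more rounds (or a "
                "manual/percentile threshold) are advised"
            )
        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) <= tol * max(abs(prev), 1.0):
                converged = True
                break

    order = np.argsort(means)
    return GmmFit(
        weights=weights[order],
        means=means[order],
        variances=variances[order],
        log_likelihood_trace=trace,
        converged=converged,
        n_iter=n_iter,
    )


def selection_threshold(fit: GmmFit) -> float:
    """Common boundary of the two weighted component densities.

    Solves the quadratic equality of weighted Gaussian log-densities and
    returns the root strictly between the two means.  When no such crossing
    exists (extreme weight/variance combinations) the midpoint of the means
    is returned and a warning is logged.
    """
    if not fit.converged:
        raise DegenerateFitError("cannot derive a threshold from a non-converged fit")
    (w1, w2) = fit.weights
    (m1, m2) = fit.means
    (v1, v2) = fit.variances
    if math.isclose(m1, m2, rel_tol=0.0, abs_tol=1e-300):
        raise DegenerateFitError("component means coincide; no boundary exists")

    lo, hi = min(m1, m2), max(m1, m2)
    # log w1 - ((x-m1)^2)/(2 v1) - log(sqrt(v1)) = log w2 - ((x-m2)^2)/(2 v2) - log(sqrt(v2))
    a = 1.0 / (2.0 * v2) - 1.0 / (2.0 * v1)
    b = m1 / v1 - m2 / v2
    c = (
        m2**2 / (2.0 * v2)
        - m1**2 / (2.0 * v1)
        + math.log(w1 / w2)
        + 0.5 * math.log(v2 / v1)
    )
    if abs(a) < 1e-18:
        roots = [-c / b] if b != 0 else []
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            roots = []
        else:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [r for r in roots if lo < r < hi]
    if inside:
        return float(inside[0] if len(inside) == 1 else min(inside, key=lambda r: abs(r - (lo + hi) / 2)))
    log.warning("no density crossing between component means; using their midpoint")
    return float((m1 + m2) / 2.0)


def select_features(scores: ScoreTable, threshold: float) -> SelectionResult:
    """Features with accumulated score strictly above ``threshold``, in
    descending score order (ties by feature id)."""
    order = scores.ranking()
    value = dict(zip(scores.feature_ids, scores.accumulated_scores))
    selected = [f for f in order if value[f] > threshold]
    if not selected:
        log.warning("empty selection: no score above threshold %.6g", threshold)
    return SelectionResult(
        threshold=float(threshold),
        selected_feature_ids=selected,
        all_scores=scores,
    )
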