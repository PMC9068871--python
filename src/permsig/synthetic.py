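"""Synthetic two-class expression matrices with planted markers.

The generator emulates the statistical structure the selection method
assumes: a heavily imbalanced two-class sample set (defaults mirror a
539-tumor / 72-normal cohort), a small number of *informative* features whose
location differs between classes by ``effect_size`` noise standard
deviations, a large background of exchangeable noise features, and optionally
a block of exactly-constant (zero-variance) decoy features.

The default noise model is log-normal: per-feature baseline log-levels are
drawn once, unit-variance Gaussian noise is added on the log scale (so
``effect_size`` reads as a log-fold-change in SD units), and values are
exponentiated — non-negative and right-skewed like expression
quantifications.  A Gaussian model (values left on the additive scale,
possibly negative) is available for classifier-theory checks.

:func:`generate_platform_pair` draws two datasets from the *same* generative
structure and multiplies designated features of the second by a scale factor,
emulating the cross-platform scale mismatch that breaks classifiers trained
on one platform and tested on another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import LabeledDataset
from .errors import InputError
from .splitting import rng_from

__all__ = ["SyntheticConfig", "generate", "generate_platform_pair"]

POSITIVE_LABEL = "tumor"
NEGATIVE_LABEL = "normal"


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults: 539 positive / 72 negative samples (the cohort imbalance the
    method is designed around), 200 features of which 5 are informative with
    a 2-SD location shift, log-normal noise, no constant decoys.
    """

    n_pos: int = 539
    n_neg: int = 72
    n_features: int = 200
    n_informative: int = 5
    effect_size: float = 2.0
    noise_model: str = "lognormal"
    n_constant: int = 0
    platform_shift: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg) < 2:
            raise InputError("each class needs at least 2 samples")
        if self.n_informative + self.n_constant > self.n_features:
            raise InputError("n_informative + n_constant must be <= n_features")
        if self.effect_size < 0:
            raise InputError("effect_size must be >= 0")
        if self.noise_model not in ("lognormal", "gaussian"):
            raise InputError("noise_model must be 'lognormal' or 'gaussian'")


def _structure(config: SyntheticConfig, rng: np.random.Generator):
    """Shared generative structure: per-feature baselines and the placement
    of informative/constant features."""
    baseline = rng.normal(loc=4.0, scale=1.0, size=config.n_features)
    perm = rng.permutation(config.n_features)
    informative = np.sort(perm[: config.n_informative])
    constant = np.sort(perm[config.n_informative : config.n_informative + config.n_constant])
    return baseline, informative, constant


def _draw(
    config: SyntheticConfig,
    baseline: np.ndarray,
    informative: np.ndarray,
    constant: np.ndarray,
    rng: np.random.Generator,
    id_prefix: str = "",
) -> tuple[LabeledDataset, list[str]]:
    n = config.n_pos + config.n_neg
    log_x = baseline[None, :] + rng.normal(0.0, 1.0, size=(n, config.n_features))
    log_x[: config.n_pos, informative] += config.effect_size
    log_x[:, constant] = baseline[constant]
    matrix = np.exp(log_x) if config.noise_model == "lognormal" else log_x

    width = max(4, len(str(config.n_features)))
    feature_ids = [f"feat-{i + 1:0{width}d}" for i in range(config.n_features)]
    sample_ids = [f"{id_prefix}S{i + 1:04d}" for i in range(n)]
    labels = np.array(
        [POSITIVE_LABEL] * config.n_pos + [NEGATIVE_LABEL] * config.n_neg, dtype=object
    )
    data = LabeledDataset(
        matrix=matrix,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        labels=labels,
        positive_label=POSITIVE_LABEL,
    )
    truth = [feature_ids[i] for i in informative]
    return data, truth


def generate(config: SyntheticConfig) -> tuple[LabeledDataset, list[str]]:
    """One dataset plus the ground-truth list of informative feature ids."""
    rng = rng_from((config.seed, 0xA))
    baseline, informative, constant = _structure(config, rng)
    return _draw(config, baseline, informative, constant, rng)


def generate_platform_pair(
    config: SyntheticConfig,
    shifted_ids: Sequence[str] | None = None,
) -> tuple[LabeledDataset, LabeledDataset, list[str]]:
    """Two same-structure datasets; designated features of the second are
    multiplied by ``config.platform_shift``.

    ``shifted_ids`` defaults to the first two informative features; pass an
    empty list to shift none.
    """
    if config.platform_shift is None:
        raise InputError("platform_shift must be set to generate a platform pair")
    rng = rng_from((config.seed, 0xA))
    baseline, informative, constant = _structure(config, rng)
    data_a, truth = _draw(config, baseline, informative, constant, rng_from((config.seed, 0xB)), "A-")
    data_b, _ = _draw(config, baseline, informative, constant, rng_from((config.seed, 0xC)), "B-")
    if shifted_ids is None:
        shifted_ids = truth[:2]
    index = {f: i for i, f in enumerate(data_b.feature_ids)}
    missing = [f for f in shifted_ids if f not in index]
    if missing:
        raise InputError(f"unknown shifted feature ids: {missing}")
    cols = [index[f] for f in shifted_ids]
    if cols:
        data_b.matrix[:, cols] *= config.platform_shift
    return data_a, data_b, truth
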