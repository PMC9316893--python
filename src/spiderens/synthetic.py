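"""Synthetic imbalanced expression-like data.

Generates the statistical structures the rest of the package is exercised
on: (i) two-class Gaussian feature tables with a configurable imbalance
ratio, a small planted informative subset (mean-shifted in the minority
class) and optional missingness; (ii) KEEL ``.dat`` benchmark fixtures; and
(iii) three-timepoint contrast sets with genes planted as differentially
expressed in all three contrasts or in single contrasts. All generation is
deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import LabeledDataset, write_keel


@dataclass
class GeneratorConfig:
    """Conditions for one imbalanced two-class dataset.

    ``effect`` is the mean shift of informative features in the minority
    class, in units of the within-class standard deviation ``noise_sd``.
    """

    n_majority: int = 90
    n_minority: int = 10
    n_features: int = 50
    n_informative: int = 10
    effect: float = 1.5
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_majority < 1 or self.n_minority < 1 or self.n_features < 1:
            raise ValueError("sample and feature counts must be positive")
        if self.n_majority < self.n_minority:
            raise ValueError("n_majority must be >= n_minority (IR >= 1)")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must lie in [0, n_features]")
        if self.effect < 0 or self.noise_sd <= 0:
            raise ValueError("effect must be >= 0 and noise_sd > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


def make_imbalanced(config: GeneratorConfig) -> tuple[LabeledDataset, np.ndarray]:
    """Draw a two-class Gaussian dataset; returns (dataset, informative indices).

    Majority samples (label 0) are N(0, noise_sd^2) in every feature;
    minority samples (label 1) have the first ``n_informative`` features
    shifted by ``effect * noise_sd``. Missing cells are placed uniformly at
    random at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_majority + config.n_minority
    x = rng.normal(0.0, config.noise_sd, size=(n, config.n_features))
    labels = np.concatenate([
        np.zeros(config.n_majority, dtype=int),
        np.ones(config.n_minority, dtype=int),
    ])
    informative = np.arange(config.n_informative)
    x[config.n_majority:, informative] += config.effect * config.noise_sd
    if config.missing_rate > 0:
        mask = rng.uniform(size=x.shape) < config.missing_rate
        x[mask] = np.nan
    data = LabeledDataset(
        x,
        labels,
        [f"g{j}" for j in range(config.n_features)],
        [f"s{i}" for i in range(n)],
    )
    return data, informative


def make_keel_fixture(config: GeneratorConfig, path: str | Path) -> LabeledDataset:
    """Write a KEEL ``.dat`` fixture readable losslessly by ``read_keel``.

    Values are rounded to the 6-significant-digit writer precision before
    returning, so the returned dataset matches the file byte-for-byte on
    round-trip. Missingness is not representable in the dialect.
    """
    if config.missing_rate != 0:
        raise ValueError("KEEL fixtures cannot carry missing values")
    data, _ = make_imbalanced(config)
    rounded = np.array([[float(f"{v:.6g}") for v in row] for row in data.features])
    data = LabeledDataset(rounded, data.labels, data.feature_names, data.sample_ids)
    write_keel(data, path)
    return data


@dataclass
class StageConfig:
    """Conditions for three-contrast stage data with planted DE genes."""

    n_per_group: int = 30
    n_genes: int = 200
    planted_up_all3: int = 0
    planted_down_all3: int = 0
    per_contrast_extra: tuple[int, int, int] = (0, 0, 0)
    effect: float = 4.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.planted_up_all3 + self.planted_down_all3 + sum(self.per_contrast_extra)
        if total > self.n_genes:
            raise ValueError("planted gene counts exceed n_genes")
        if self.n_per_group < 2 or self.n_genes < 1:
            raise ValueError("n_per_group must be >= 2 and n_genes >= 1")
        if self.effect < 0 or self.noise_sd <= 0:
            raise ValueError("effect must be >= 0 and noise_sd > 0")


def make_stage_data(
    config: StageConfig,
) -> tuple[list[LabeledDataset], dict[str, np.ndarray]]:
    """Three two-group contrasts emulating control-vs-patient and follow-ups.

    Each contrast is (reference group = label 0, condition group = label 1),
    both Gaussian. Genes in ``planted_up_all3`` get a +effect shift in the
    condition group of all three contrasts, ``planted_down_all3`` a −effect
    shift; per-contrast extras are up-shifted in one contrast only. Returns
    the contrasts and the ground-truth index sets (disjoint by construction).
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    up3 = np.arange(config.planted_up_all3)
    down3 = np.arange(config.planted_up_all3,
                      config.planted_up_all3 + config.planted_down_all3)
    offset = config.planted_up_all3 + config.planted_down_all3
    extras = []
    for e in config.per_contrast_extra:
        extras.append(np.arange(offset, offset + e))
        offset += e

    shift = config.effect * config.noise_sd
    contrasts: list[LabeledDataset] = []
    for c in range(3):
        x = rng.normal(0.0, config.noise_sd, size=(2 * config.n_per_group, g))
        cond = slice(config.n_per_group, 2 * config.n_per_group)
        if len(up3):
            x[cond, up3] += shift
        if len(down3):
            x[cond, down3] -= shift
        if len(extras[c]):
            x[cond, extras[c]] += shift
        labels = np.concatenate([
            np.zeros(config.n_per_group, dtype=int),
            np.ones(config.n_per_group, dtype=int),
        ])
        contrasts.append(LabeledDataset(
            x,
            labels,
            [f"g{j}" for j in range(g)],
            [f"c{c}_s{i}" for i in range(2 * config.n_per_group)],
        ))
    truth = {
        "up_all3": up3,
        "down_all3": down3,
        "extra_c0": extras[0],
        "extra_c1": extras[1],
        "extra_c2": extras[2],
    }
    return contrasts, truth
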