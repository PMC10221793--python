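"""Synthetic beta-value matrices with planted group structure.

Emulates a blood-methylation case/control array study: three balanced
groups (control, hypertensive, pre-hypertensive; 44 each by default), a
CpG-by-sample matrix of beta values, and a small set of "informative" CpGs
whose class means are shifted. Every cell is drawn from a beta distribution
in its mean/precision parameterization,

    x ~ Beta(mu * phi, (1 - mu) * phi),

so values are natively bounded in [0, 1] and the noise level is controlled
by the single concentration parameter ``phi`` (variance
mu(1-mu)/(phi+1)). Null CpGs share one mean across classes, drawn per CpG
from a bimodal baseline mixture (mass near 0.1 and 0.9 plus a uniform
middle component) mimicking the characteristic two-humped distribution of
array methylomes. Informative CpGs shift by ``delta`` in the hypertensive
class and by ``pre_fraction * delta`` in the pre-hypertensive class, with
a per-CpG random sign so both hypo- and hypermethylation occur; the
pre-hypertensive group therefore sits between control and hypertensive, the
ordering the downstream classifiers are expected to exploit.

Missing cells are planted uniformly at random at a small rate, emulating
failed probes, and are left as NaN for the QC/imputation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .matrix import MethylationMatrix, SampleLabels

#: baseline mixture: (weight, component) with components named for readability
_BASELINE_LOW = (5.0, 45.0)     # Beta(5,45): mean 0.10, unmethylated mode
_BASELINE_HIGH = (45.0, 5.0)    # Beta(45,5): mean 0.90, methylated mode
_BASELINE_WEIGHTS = (0.4, 0.4, 0.2)  # low, high, uniform middle
_BASELINE_MID = (0.2, 0.8)      # uniform support of the middle component
#: informative baselines are drawn from this band so a +/- delta shift can fit
_INFORMATIVE_BAND = (0.15, 0.85)
_EDGE = 0.02                    # class means kept at least this far from {0, 1}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study design knobs for the generator.

    Defaults reproduce the desk-scale test bed: 5,000 CpGs, balanced
    44/44/44 groups, 200 informative CpGs shifted by delta = 0.15 (half of
    that in the pre-hypertensive group), beta concentration 30, and 0.5%
    missing cells.
    """

    n_cpgs: int = 5000
    group_sizes: tuple[int, int, int] = (44, 44, 44)
    n_informative: int = 200
    delta: float = 0.15
    pre_fraction: float = 0.5
    precision: float = 30.0
    missing_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.n_cpgs < 1:
            raise ConfigError("n_cpgs must be positive")
        if self.n_informative < 0 or self.n_informative > self.n_cpgs:
            raise ConfigError("n_informative must lie in [0, n_cpgs]")
        if not 0.0 <= self.delta <= 0.5:
            raise ConfigError("delta must lie in [0, 0.5]")
        if not 0.0 <= self.pre_fraction <= 1.0:
            raise ConfigError("pre_fraction must lie in [0, 1]")
        if self.precision <= 0:
            raise ConfigError("precision must be positive")
        if not 0.0 <= self.missing_rate <= 0.05:
            raise ConfigError("missing_rate must lie in [0, 0.05]")
        if any(g < 0 for g in self.group_sizes) or sum(self.group_sizes) < 1:
            raise ConfigError("group_sizes must be non-negative with at least one sample")
        lo, hi = _INFORMATIVE_BAND
        # worst case is a mid-band baseline: at least one shift direction must fit
        worst = max((lo + hi) / 2 - _EDGE, 1.0 - _EDGE - (lo + hi) / 2)
        if self.delta > worst:
            raise ConfigError(
                f"delta={self.delta} infeasible: a mid-band baseline cannot shift "
                f"by delta in either direction while staying inside (0, 1)")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated dataset: which CpGs carry signal, and how much."""

    informative_cpg_ids: frozenset[str]
    class_means: pd.DataFrame = field(repr=False)  # CpG x class (0,1,2) true means

    def to_dict(self) -> dict:
        return {
            "informative_cpg_ids": sorted(self.informative_cpg_ids),
            "class_means": {str(c): self.class_means[c].round(6).to_dict()
                            for c in self.class_means.columns},
        }


def _baseline_means(rng: np.random.Generator, n: int) -> np.ndarray:
    comp = rng.choice(3, size=n, p=_BASELINE_WEIGHTS)
    out = np.empty(n)
    low = comp == 0
    high = comp == 1
    mid = comp == 2
    out[low] = rng.beta(*_BASELINE_LOW, size=int(low.sum()))
    out[high] = rng.beta(*_BASELINE_HIGH, size=int(high.sum()))
    out[mid] = rng.uniform(*_BASELINE_MID, size=int(mid.sum()))
    return np.clip(out, _EDGE, 1.0 - _EDGE)


def generate(config: SyntheticConfig
             ) -> tuple[MethylationMatrix, SampleLabels, SyntheticTruth]:
    """Draw one reproducible dataset: matrix, labels and ground truth.

    The first ``n_informative`` CpG ids (after shuffling) are informative;
    classes are laid out in blocks control / hypertensive / pre-hypertensive
    with ids ``S0001``... Identical configs (including seed) give identical
    output bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_cpgs, config.n_informative
    g0, g1, g2 = config.group_sizes
    m = g0 + g1 + g2

    cpg_ids = np.array([f"cg{i:08d}" for i in range(n)])
    sample_ids = [f"S{j:04d}" for j in range(m)]
    classes = np.concatenate([np.zeros(g0, int), np.ones(g1, int), np.full(g2, 2)])

    informative_idx = rng.choice(n, size=k, replace=False) if k else np.array([], int)
    baseline = _baseline_means(rng, n)
    # informative baselines redrawn from the feasible band
    baseline[informative_idx] = rng.uniform(*_INFORMATIVE_BAND, size=k)

    # per-class mean matrix (n x 3): start from the shared baseline
    class_means = np.repeat(baseline[:, None], 3, axis=1)
    if k:
        sign = rng.choice([-1.0, 1.0], size=k)
        # flip any shift that would leave (0,1); both infeasible is a config error
        shifted = baseline[informative_idx] + sign * config.delta
        flip = (shifted < _EDGE) | (shifted > 1.0 - _EDGE)
        sign[flip] *= -1.0
        shifted = baseline[informative_idx] + sign * config.delta
        if np.any((shifted < _EDGE) | (shifted > 1.0 - _EDGE)):
            raise ConfigError("delta shift leaves (0,1) for some informative baseline")
        class_means[informative_idx, 1] = shifted
        class_means[informative_idx, 2] = (baseline[informative_idx]
                                           + config.pre_fraction * sign * config.delta)

    mu = class_means[:, classes]                      # n x m cell means
    a = mu * config.precision
    b = (1.0 - mu) * config.precision
    values = rng.beta(a, b)

    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = np.nan

    matrix = MethylationMatrix(pd.DataFrame(values, index=cpg_ids, columns=sample_ids))
    labels = SampleLabels(tuple(sample_ids), tuple(int(c) for c in classes))
    truth = SyntheticTruth(
        informative_cpg_ids=frozenset(cpg_ids[informative_idx]),
        class_means=pd.DataFrame(class_means, index=cpg_ids, columns=[0, 1, 2]),
    )
    return matrix, labels, truth
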