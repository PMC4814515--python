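"""Sampling variability of observed accuracy and label-quality ceilings.

An observed accuracy is a binomial proportion: over test samples of N
subjects it scatters around the population accuracy with
SD = sqrt(acc_true * (100% - acc_true) / N).  For support-vector machines
the cross-validation spread is driven by the subjects that actually carry
the model, so N_SV can stand in for N as a heuristic.  Imperfect expert
labeling (a "silver standard" with interclass kappa) mislabels a fraction
(1 - kappa) / 2 of subjects and caps the observable accuracy at
acc = kappa * acc0 + (1 - kappa) / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = [
    "AccuracyEstimate",
    "LabelQuality",
    "sampling_sd",
    "accuracy_interval",
    "estimate_accuracy",
    "sv_based_sd",
    "sv_fraction",
    "silver_standard_accuracy",
    "invert_silver_standard",
    "mislabel_fraction",
    "binomial_interval_coverage",
]

_CONVENTIONS = ("two-sigma", "normal-1.96")


@dataclass(frozen=True)
class AccuracyEstimate:
    """An accuracy with its binomial sampling SD and interval bounds."""

    acc_true: float  #: population accuracy, percent
    n: int  #: number of test subjects
    sd: float  #: sampling SD, accuracy points
    ci_low: float  #: lower interval bound, percent
    ci_high: float  #: upper interval bound, percent
    convention: str = "two-sigma"

    def to_dict(self) -> dict:
        return {
            "acc_true": self.acc_true,
            "n": self.n,
            "sd": self.sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "convention": self.convention,
        }


@dataclass(frozen=True)
class LabelQuality:
    """Quality of the expert labeling, as an interclass kappa in [0, 1]."""

    kappa: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")


def _check(acc_true: float, n: int) -> None:
    if not 0.0 <= acc_true <= 100.0:
        raise ValueError("accuracy must lie in [0, 100] percent")
    if n < 1:
        raise ValueError("invalid sample size: n must be >= 1")


def sampling_sd(acc_true: float, n: int) -> float:
    """Binomial SD of an observed accuracy, in accuracy points.

    sqrt(acc_true * (100 - acc_true) / n); maximal at 50% and shrinking
    as 1 / sqrt(n).
    """
    _check(acc_true, n)
    return math.sqrt(acc_true * (100.0 - acc_true) / n)


def accuracy_interval(
    acc_true: float, n: int, convention: str = "two-sigma"
) -> tuple[float, float]:
    """Normal-approximation interval around the population accuracy.

    The default ``two-sigma`` convention (acc_true +/- 2 SD) matches the
    ~95% ranges conventionally printed alongside the SD formula;
    ``normal-1.96`` uses the exact 95% normal quantile.
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"unknown interval convention: {convention!r}")
    z = 2.0 if convention == "two-sigma" else 1.959963984540054
    sd = sampling_sd(acc_true, n)
    return acc_true - z * sd, acc_true + z * sd


def estimate_accuracy(
    acc_true: float, n: int, convention: str = "two-sigma"
) -> AccuracyEstimate:
    """Bundle an accuracy with its sampling SD and interval bounds."""
    low, high = accuracy_interval(acc_true, n, convention)
    return AccuracyEstimate(
        acc_true=acc_true,
        n=n,
        sd=sampling_sd(acc_true, n),
        ci_low=low,
        ci_high=high,
        convention=convention,
    )


def sv_based_sd(acc_true: float, n_sv: int) -> float:
    """Heuristic SD of cross-validation accuracy using N_SV in place of N.

    Only the support vectors move the separating hyperplane when subjects
    are left out, so their count approximates the effective sample size of
    the CV spread.
    """
    return sampling_sd(acc_true, n_sv)


def sv_fraction(n_sv: int, n: int) -> float:
    """Support vectors as a percentage of the training sample."""
    if n < 1:
        raise ValueError("invalid counts: n must be >= 1")
    if not 0 <= n_sv <= n:
        raise ValueError("invalid counts: need 0 <= n_sv <= n")
    return 100.0 * n_sv / n


def silver_standard_accuracy(acc0: float, quality: LabelQuality) -> float:
    """Observed accuracy under imperfect labels: kappa * acc0 + (1 - kappa)/2.

    Computed on the fraction scale and returned as percent.  For acc0 above
    chance and kappa < 1 the observable accuracy is strictly below acc0;
    kappa = 0 pins every model at 50%.
    """
    if not 0.0 <= acc0 <= 100.0:
        raise ValueError("accuracy must lie in [0, 100] percent")
    a0 = acc0 / 100.0
    return 100.0 * (quality.kappa * a0 + (1.0 - quality.kappa) / 2.0)


def invert_silver_standard(acc: float, quality: LabelQuality) -> float:
    """Recover the gold-standard accuracy from a silver-standard one."""
    if quality.kappa == 0.0:
        raise ValueError("kappa = 0: labels carry no information, acc0 undefined")
    a = acc / 100.0
    return 100.0 * (a - (1.0 - quality.kappa) / 2.0) / quality.kappa


def mislabel_fraction(quality: LabelQuality) -> float:
    """Fraction of cases mislabeled by the experts, (1 - kappa) / 2."""
    return (1.0 - quality.kappa) / 2.0


def binomial_interval_coverage(acc_true: float, n: int, convention: str = "two-sigma") -> float:
    """Exact binomial probability that an observed accuracy falls inside
    the normal-approximation interval.

    Comparison oracle for small n: the probability, under Binomial(n,
    acc_true/100), that 100 * k / n lies within ``accuracy_interval``.
    """
    low, high = accuracy_interval(acc_true, n, convention)
    k_low = int(np.ceil(low / 100.0 * n - 1e-12))
    k_high = int(np.floor(high / 100.0 * n + 1e-12))
    p = acc_true / 100.0
    return float(binom.cdf(k_high, n, p) - binom.cdf(k_low - 1, n, p))
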