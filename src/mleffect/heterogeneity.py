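"""The petal model: sample heterogeneity and its effect on accuracy.

A heterogeneous patient sample is pictured as H homogeneous subgroups
("petals") that share a core of discriminative features; any two petals
share a fraction f of their discriminative pattern.  A linear model trained
on the mixture is the average of the (unit-norm) subgroup models, which
attenuates the homogeneous-sample effect size d0 by

    sqrt((1 + (H - 1) f) / H)          (within-sample heterogeneity)

reducing to the two-subgroup form sqrt((1 + f) / 2) at H = 2.  Applying a
model to an independent sample that shares only a fraction f of
discriminative features scales the effect size by f outright
(between-sample heterogeneity).  On the accuracy scale the two effects are
approximated by the log rules  dacc ~ 53% * log10(f)  and
dacc ~ 26% * log10((1 + f) / 2), tangent approximations that are accurate
when both accuracies lie in roughly the 70-90% band.

The overlap fraction f is observable: for two linear models it equals the
cosine of the angle between their weight vectors, and for a train/test
accuracy pair it can be estimated by inverting the accuracy model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .effectsize import accuracy_from_effect_size, effect_size_from_accuracy
from .uncertainty import LabelQuality, silver_standard_accuracy

__all__ = [
    "HeterogeneitySpec",
    "TrainTestOverlap",
    "NoiseModel",
    "LinearModel",
    "within_sample_attenuation",
    "between_sample_effect_size",
    "accuracy_drop_between",
    "accuracy_drop_within",
    "estimate_overlap",
    "train_test_effect_size",
    "compose_noise",
    "weight_overlap",
    "predict_accuracy_curve",
    "accuracy_curve",
    "train_test_overlap_attenuation",
]

#: Train-accuracy band (percent) in which the log-rule approximations are
#: advertised; outside it they still compute but a warning is emitted.
VALIDITY_BAND = (70.0, 90.0)


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Parameters of a (possibly heterogeneous) sample under the petal model.

    Attributes
    ----------
    d0
        ML effect size a homogeneous sample would attain.
    f
        Pairwise shared-feature fraction between homogeneous subsamples,
        in [-1, 1].
    n0
        Homogeneous-subsample size per group (subjects).
    h
        Within-sample heterogeneity fold (real, >= 1).
    """

    d0: float
    f: float = 0.0
    n0: float = 50.0
    h: float = 1.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.f <= 1.0:
            raise ValueError("overlap fraction f must lie in [-1, 1]")
        if self.h < 1.0:
            raise ValueError("heterogeneity fold H must be >= 1")
        if self.n0 < 1.0:
            raise ValueError("homogeneous subsample size N0 must be >= 1")
        if 1.0 + (self.h - 1.0) * self.f < 0.0:
            raise ValueError(f"petal model undefined for this (H, f): ({self.h}, {self.f})")


@dataclass(frozen=True)
class TrainTestOverlap:
    """Discrete petal overlap between a training and a test population.

    The training population has H petals, the test population H' petals,
    of which T (0 <= T <= min(H, H')) are shared; any two petals overlap
    pairwise by the core fraction f.
    """

    h: int
    h_prime: int
    t: int
    f: float = 0.0

    def __post_init__(self) -> None:
        if self.h < 1 or self.h_prime < 1:
            raise ValueError("petal folds must be integers >= 1")
        if not 0 <= self.t <= min(self.h, self.h_prime):
            raise ValueError("shared fold T must satisfy 0 <= T <= min(H, H')")
        if not -1.0 <= self.f <= 1.0:
            raise ValueError("overlap fraction f must lie in [-1, 1]")
        if 1.0 + (self.h - 1) * self.f <= 0.0:
            raise ValueError(f"petal model undefined for this (H, f): ({self.h}, {self.f})")


@dataclass(frozen=True)
class NoiseModel:
    """Decomposition of the output spread into biological and noise parts.

    ``sigma_y`` (training-sample output SD) defaults to the composition
    sqrt(sigma_biol^2 + sigma_exp^2); ``sigma_yt`` (test-sample output SD)
    defaults to ``sigma_y``.
    """

    sigma_biol: float = 0.0
    sigma_exp: float = 0.0
    sigma_y: float | None = None
    sigma_yt: float | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_biol", "sigma_exp"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"invalid SD: {name} must be >= 0")
        for name in ("sigma_y", "sigma_yt"):
            value = getattr(self, name)
            if value is not None and value < 0.0:
                raise ValueError(f"invalid SD: {name} must be >= 0")

    @property
    def sigma_y_total(self) -> float:
        if self.sigma_y is not None:
            return self.sigma_y
        return compose_noise(self.sigma_biol, self.sigma_exp)

    @property
    def sigma_yt_total(self) -> float:
        return self.sigma_yt if self.sigma_yt is not None else self.sigma_y_total


@dataclass(frozen=True)
class LinearModel:
    """A linear classifier y = w.x + b."""

    weights: np.ndarray
    offset: float = 0.0
    n_sv: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float).ravel())

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.weights))

    def normalized(self) -> np.ndarray:
        n = self.norm
        if n == 0.0:
            raise ValueError("zero weight vector")
        return self.weights / n

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features, dtype=float) @ self.weights + self.offset


def within_sample_attenuation(f: float, h: float) -> float:
    """Effect-size attenuation from H-fold within-sample heterogeneity.

    sqrt((1 + (H - 1) f) / H): the trained model averages H unit-norm
    subgroup weight vectors with common pairwise overlap f.  Equals 1 at
    H = 1 or f = 1, and sqrt((1 + f) / 2) at H = 2.
    """
    if h < 1.0:
        raise ValueError("heterogeneity fold H must be >= 1")
    arg = 1.0 + (h - 1.0) * f
    if arg < 0.0:
        raise ValueError(f"petal model undefined for this (H, f): ({h}, {f})")
    return math.sqrt(arg / h)


def between_sample_effect_size(d_ml: float, f: float) -> float:
    """Effect size in an independent sample sharing a fraction f of features.

    d_ML -> f * d_ML; negative f (opposite-direction features) yields a
    below-chance expected test accuracy.
    """
    if not -1.0 <= f <= 1.0:
        raise ValueError("overlap fraction f must lie in [-1, 1]")
    return f * d_ml


def _warn_band(train_acc: float | None) -> None:
    if train_acc is not None and not VALIDITY_BAND[0] <= train_acc <= VALIDITY_BAND[1]:
        warnings.warn(
            f"log-rule approximation is advertised for train accuracies in "
            f"{VALIDITY_BAND[0]:.0f}-{VALIDITY_BAND[1]:.0f}%; got {train_acc:.1f}%",
            stacklevel=3,
        )


def accuracy_drop_between(f: float, train_accuracy: float | None = None) -> float:
    """Between-sample accuracy loss in points: -53 * log10(f).

    Tangent approximation to the exact Phi-based drop; accurate when both
    train and test accuracies lie in roughly the 70-90% band.  Pass
    ``train_accuracy`` to get a warning outside that band.
    """
    if f <= 0.0:
        raise ValueError("approximation undefined for f <= 0")
    if f > 1.0:
        raise ValueError("overlap fraction f must be <= 1")
    _warn_band(train_accuracy)
    return -53.0 * math.log10(f)


def accuracy_drop_within(f: float, train_accuracy: float | None = None) -> float:
    """Within-sample (two-subgroup) accuracy loss: -26 * log10((1 + f) / 2).

    Loss of CV accuracy of a model trained on two mixed subgroups with
    overlap f, relative to a homogeneous sample of the same size.
    """
    if f <= -1.0:
        raise ValueError("approximation undefined for f <= -1")
    if f > 1.0:
        raise ValueError("overlap fraction f must be <= 1")
    _warn_band(train_accuracy)
    return -26.0 * math.log10((1.0 + f) / 2.0)


def estimate_overlap(acc_train: float, acc_test: float, method: str = "exact") -> float:
    """Estimate the between-sample overlap f from a train/test accuracy pair.

    ``exact`` inverts the accuracy model: f = Phi^-1(acc_test/100) /
    Phi^-1(acc_train/100).  ``log-approx`` inverts the 53-point rule:
    f = 10 ** ((acc_test - acc_train) / 53).
    """
    if method == "exact":
        if acc_train == 50.0:
            raise ValueError("train effect size zero, f undefined")
        if not (50.0 < acc_train < 100.0 and 0.0 < acc_test < 100.0):
            raise ValueError("exact method needs acc_train in (50, 100) and acc_test in (0, 100)")
        return float(ndtri(acc_test / 100.0) / ndtri(acc_train / 100.0))
    if method == "log-approx":
        _warn_band(acc_train)
        return float(10.0 ** ((acc_test - acc_train) / 53.0))
    raise ValueError(f"unknown method: {method!r}")


def train_test_effect_size(d_ml: float, f: float, noise: NoiseModel) -> float:
    """Effect size in an independent test sample: (sigma_y / sigma_yT) * f * d_ML.

    Composes the overlap attenuation with a change of output spread between
    training and test samples (broader test spread lowers the effect size;
    e.g. doubled noise has the same effect as a 50% overlap).
    """
    sigma_y = noise.sigma_y_total
    sigma_yt = noise.sigma_yt_total
    if sigma_yt == 0.0:
        raise ValueError("degenerate test variance: sigma_yT must be > 0")
    return (sigma_y / sigma_yt) * between_sample_effect_size(d_ml, f)


def compose_noise(sigma_biol: float, sigma_exp: float) -> float:
    """Total output SD from biological and measurement parts (in quadrature)."""
    if sigma_biol < 0.0 or sigma_exp < 0.0:
        raise ValueError("invalid SD: components must be >= 0")
    return math.hypot(sigma_biol, sigma_exp)


def weight_overlap(m1, m2) -> tuple[float, float]:
    """Overlap f = cos(theta) between two linear models' weight vectors.

    Returns ``(f, theta_degrees)``.  Accepts :class:`LinearModel` instances
    or plain weight arrays.  f is the dot product of the normalized vectors,
    in [-1, 1]; angles beyond 90 degrees (negative f) indicate features
    discriminative in opposite directions.
    """
    w1 = m1.weights if hasattr(m1, "weights") else np.asarray(m1, dtype=float).ravel()
    w2 = m2.weights if hasattr(m2, "weights") else np.asarray(m2, dtype=float).ravel()
    if w1.shape != w2.shape:
        raise ValueError("weight vectors must have equal dimension")
    n1 = np.linalg.norm(w1)
    n2 = np.linalg.norm(w2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("zero weight vector")
    f = float(np.clip(w1 @ w2 / (n1 * n2), -1.0, 1.0))
    return f, math.degrees(math.acos(f))


def predict_accuracy_curve(spec: HeterogeneitySpec, n_per_group, ceiling_kappa: float | None = None):
    """Expected CV accuracy (percent) of a sample of n subjects per group.

    The sample is modeled as H_eff = max(1, n / N0) homogeneous subgroups
    (real-valued; below N0 the sample is homogeneous and the curve
    plateaus), so the accuracy is 100 * Phi(d0 * sqrt((1 + (H_eff - 1) f)
    / H_eff) / 2).  An optional label-quality ceiling ``ceiling_kappa``
    applies the silver-standard map to the result.
    """
    n = np.asarray(n_per_group, dtype=float)
    if np.any(n < 1):
        raise ValueError("n_per_group must be >= 1")
    h_eff = np.maximum(1.0, n / spec.n0)
    arg = (1.0 + (h_eff - 1.0) * spec.f) / h_eff
    if np.any(arg < 0.0):
        raise ValueError("petal model undefined: 1 + (H - 1) f < 0 on the curve")
    d = spec.d0 * np.sqrt(arg)
    acc = 100.0 * ndtr(d / 2.0)
    if ceiling_kappa is not None:
        q = LabelQuality(ceiling_kappa)
        acc = np.vectorize(lambda a: silver_standard_accuracy(a, q))(acc)
    return acc + 0.0


def accuracy_curve(
    spec: HeterogeneitySpec, n_values, ceiling_kappa: float | None = None
) -> list[dict]:
    """Tabulate the accuracy-vs-N curve as JSON-ready records."""
    out = []
    for n in np.asarray(n_values, dtype=float).ravel():
        h_eff = max(1.0, n / spec.n0)
        d = spec.d0 * within_sample_attenuation(spec.f, h_eff)
        out.append(
            {
                "n_per_group": float(n),
                "H_eff": h_eff,
                "d_ml": d,
                "accuracy_pct": float(predict_accuracy_curve(spec, n, ceiling_kappa)),
            }
        )
    return out


def train_test_overlap_attenuation(overlap: TrainTestOverlap) -> float:
    """Expected test-sample attenuation for discrete T-fold petal overlap.

    With equal unit petal weight vectors and common pairwise overlap f, the
    trained direction is w = sum_i w_i / |sum_i w_i| with
    |sum_i w_i|^2 = H + H (H - 1) f.  A test petal shared with the training
    population projects onto w as (1 + (H - 1) f) / |sum w_i|; an unshared
    petal as H f / |sum w_i|.  The test sample mixes H' petals of which T
    are shared, giving the weighted mean of the two projections.  Reduces
    to ``within_sample_attenuation(f, H)`` at H' = T = H.
    """
    h, hp, t, f = overlap.h, overlap.h_prime, overlap.t, overlap.f
    norm_sq = h + h * (h - 1) * f
    shared = (1.0 + (h - 1) * f) / math.sqrt(norm_sq)
    unshared = h * f / math.sqrt(norm_sq)
    return (t * shared + (hp - t) * unshared) / hp
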