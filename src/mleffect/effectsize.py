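"""Effect sizes for binary classifiers and their link to accuracy.

A trained binary classifier maps each subject's feature vector to a single
decision value ``y``.  The standardized separation of the two groups'
decision-value distributions is the machine-learning effect size

    d_ML = (mean(y | patients) - mean(y | controls)) / sigma_y,

with ``sigma_y = sqrt(s0**2 / 2 + s1**2 / 2)`` the (unweighted) pooled SD of
the two groups.  Under an equal-variance normal model the fraction of
subjects on the correct side of the midpoint threshold -- Cohen's
non-overlap U2 -- is ``Phi(d_ML / 2)``, which makes d_ML interconvertible
with classification accuracy, with the binormal AUC and with the t statistic
of the group difference.  Because diagnostic accuracy demands far larger
separations than group-level statistics, the qualification scale used here
calls d = 0.8 (66% accuracy) merely "modest".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import norm

__all__ = [
    "ONE_SAMPLE",
    "TWO_SAMPLE",
    "GroupScores",
    "MLEffectSize",
    "CohensEffect",
    "QualificationScale",
    "TTestResult",
    "DEFAULT_SCALE",
    "compute_effect_size",
    "accuracy_from_effect_size",
    "effect_size_from_accuracy",
    "effect_size_from_auc",
    "t_from_effect_size",
    "qualify_effect_size",
]

#: t-statistic conventions.  ``ONE_SAMPLE`` treats N as the number of
#: measurements of the group difference (t = d * sqrt(N)); ``TWO_SAMPLE``
#: is the equal-group two-sample formula with N/2 subjects per group,
#: t = d * sqrt(N) / 2.  The two-sample form is the default for
#: case-control classifier studies.
ONE_SAMPLE = "one-sample"
TWO_SAMPLE = "two-sample"


@dataclass(frozen=True)
class GroupScores:
    """Per-subject classifier decision values with binary group labels.

    Parameters
    ----------
    labels
        Group membership per subject; 0 = control, 1 = patient.
    scores
        Real-valued classifier output ``y`` per subject.
    """

    labels: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        scores = np.asarray(self.scores, dtype=float)
        if labels.ndim != 1 or labels.shape != scores.shape:
            raise ValueError("labels and scores must be 1-D arrays of equal length")
        if labels.size and not np.all(np.isin(labels, (0, 1))):
            raise ValueError("labels must be strictly binary (0 = control, 1 = patient)")
        object.__setattr__(self, "labels", labels.astype(int))
        object.__setattr__(self, "scores", scores)

    @classmethod
    def from_groups(cls, controls, patients) -> "GroupScores":
        """Build from two separate score arrays (controls, patients)."""
        controls = np.asarray(controls, dtype=float).ravel()
        patients = np.asarray(patients, dtype=float).ravel()
        labels = np.concatenate(
            [np.zeros(controls.size, dtype=int), np.ones(patients.size, dtype=int)]
        )
        return cls(labels, np.concatenate([controls, patients]))

    def group(self, which: int) -> np.ndarray:
        return self.scores[self.labels == which]


@dataclass(frozen=True)
class MLEffectSize:
    """Machine-learning effect size and the group statistics behind it."""

    delta_y: float  #: y1 - y0, the separation strength
    s_y0: float  #: control-group sample SD (n-1 denominator)
    s_y1: float  #: patient-group sample SD (n-1 denominator)
    sigma_y: float  #: pooled SD, sqrt(s0^2/2 + s1^2/2)
    d_ml: float  #: delta_y / sigma_y

    @property
    def accuracy_pct(self) -> float:
        """Expected accuracy 100 * Phi(d_ML / 2), percent."""
        return accuracy_from_effect_size(self.d_ml)

    def to_dict(self) -> dict:
        """JSON-ready record including accuracy and qualification label."""
        return {
            "delta_y": self.delta_y,
            "s_y0": self.s_y0,
            "s_y1": self.s_y1,
            "sigma_y": self.sigma_y,
            "d_ml": self.d_ml,
            "accuracy_pct": self.accuracy_pct,
            "qualification": qualify_effect_size(self.d_ml),
        }


@dataclass(frozen=True)
class CohensEffect:
    """A standardized mean difference with the sample size and t convention."""

    d: float
    n_total: int
    design: str = TWO_SAMPLE

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")


class TTestResult(NamedTuple):
    t: float
    p: float


@dataclass(frozen=True)
class QualificationScale:
    """Accuracy breakpoints (percent) and labels for qualifying d_ML.

    The default scale is <60% "small", 60-70% "modest", 70-80% "medium",
    >80% "large".  The stored d breakpoints are the conventional printed
    values (0.50, 1.05, 1.68); note 2*Phi^-1(0.60) = 0.5067, so the first
    breakpoint is consistent with its accuracy only to ~0.01.
    """

    acc_breakpoints: tuple = (60.0, 70.0, 80.0)
    labels: tuple = ("small", "modest", "medium", "large")
    d_breakpoints: tuple = (0.50, 1.05, 1.68)

    def __post_init__(self) -> None:
        if list(self.acc_breakpoints) != sorted(self.acc_breakpoints):
            raise ValueError("accuracy breakpoints must be strictly increasing")
        if len(self.labels) != len(self.acc_breakpoints) + 1:
            raise ValueError("need one label more than breakpoints")
        for acc, d in zip(self.acc_breakpoints, self.d_breakpoints):
            if abs(effect_size_from_accuracy(acc) - d) > 0.02:
                raise ValueError(
                    f"d breakpoint {d} inconsistent with accuracy breakpoint {acc}%"
                )

    def qualify(self, d_ml: float) -> str:
        acc = accuracy_from_effect_size(abs(d_ml))
        idx = int(np.searchsorted(self.acc_breakpoints, acc, side="left"))
        return self.labels[idx]


def compute_effect_size(scores: GroupScores) -> MLEffectSize:
    """Compute the ML effect size d_ML = delta_y / sigma_y from labeled scores.

    Sample SDs use the n-1 denominator and the pooled SD is the unweighted
    root-mean-square of the two group SDs.

    Raises
    ------
    ValueError
        If either group is missing or has fewer than two subjects
        ("missing group"), or if the pooled SD is zero ("degenerate scores").
    """
    y0 = scores.group(0)
    y1 = scores.group(1)
    if y0.size < 2 or y1.size < 2:
        raise ValueError("missing group: each group needs at least 2 subjects")
    s0 = float(np.std(y0, ddof=1))
    s1 = float(np.std(y1, ddof=1))
    sigma = math.sqrt(0.5 * s0 * s0 + 0.5 * s1 * s1)
    delta = float(np.mean(y1) - np.mean(y0))
    if sigma == 0.0:
        raise ValueError("degenerate scores: pooled SD is zero")
    return MLEffectSize(delta_y=delta, s_y0=s0, s_y1=s1, sigma_y=sigma, d_ml=delta / sigma)


def accuracy_from_effect_size(d_ml):
    """Expected classification accuracy 100 * Phi(d_ML / 2), in percent."""
    return 100.0 * ndtr(np.asarray(d_ml, dtype=float) / 2.0) + 0.0


def effect_size_from_accuracy(acc):
    """Invert the accuracy model: d_ML = 2 * Phi^-1(acc / 100).

    ``acc`` is a percentage strictly between 0 and 100.
    """
    acc = np.asarray(acc, dtype=float)
    if np.any(acc <= 0.0) or np.any(acc >= 100.0):
        raise ValueError("accuracy out of range (0, 100)")
    return 2.0 * ndtri(acc / 100.0) + 0.0


def effect_size_from_auc(auc):
    """d_ML from the area under the ROC curve.

    Uses the equal-variance binormal identity AUC = Phi(d / sqrt(2)),
    i.e. d = sqrt(2) * Phi^-1(AUC).  ``auc`` is a fraction in (0, 1).
    """
    auc = np.asarray(auc, dtype=float)
    if np.any(auc <= 0.0) or np.any(auc >= 1.0):
        raise ValueError("AUC out of range (0, 1)")
    return math.sqrt(2.0) * ndtri(auc) + 0.0


def t_from_effect_size(eff: CohensEffect) -> TTestResult:
    """t statistic (and two-sided normal-approximation p) for an effect size.

    ``one-sample``: t = d * sqrt(N) -- N observations of the difference.
    ``two-sample``: t = d * sqrt(N) / 2 -- equal groups of N/2 subjects.
    The p-value uses the standard normal approximation to the t
    distribution (adequate at the sample sizes considered here).
    """
    if eff.design == ONE_SAMPLE:
        t = eff.d * math.sqrt(eff.n_total)
    elif eff.design == TWO_SAMPLE:
        t = eff.d * math.sqrt(eff.n_total) / 2.0
    else:
        raise ValueError(f"unknown t convention: {eff.design!r}")
    p = 2.0 * norm.sf(abs(t))
    return TTestResult(t=t, p=float(p))


DEFAULT_SCALE = QualificationScale()


def qualify_effect_size(d_ml: float, scale: QualificationScale = DEFAULT_SCALE) -> str:
    """Map |d_ML| to a qualification label via its expected accuracy."""
    return scale.qualify(d_ml)
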