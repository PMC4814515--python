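"""Fitting the heterogeneity accuracy-vs-N curve to published study tables.

The accuracy of case-control classifier studies tends to fall with sample
size: larger samples are inevitably more heterogeneous.  The petal model
turns that decline into a parametric curve

    acc(n) = 100 * Phi(d0 / 2 * sqrt((1 + (H - 1) f) / H)),  H = max(1, n / N0),

with d0 the homogeneous-sample effect size, N0 the largest sample size a
homogeneous group can reach, and f the shared-core fraction.  The reference
parameter set (d0 = 2.00, f = 0, N0 = 50) is shipped as a descriptive
default; a bounded least-squares fit (grid search plus Nelder-Mead
refinement on unit-scaled parameters, with optional case-resampling
bootstrap CIs) is available for tables with enough points.  For train/test
study pairs the between-sample overlap f is estimated per record from the
accuracy pair.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import norm

from .heterogeneity import HeterogeneitySpec, estimate_overlap, predict_accuracy_curve
from .io import DataError
from .uncertainty import sampling_sd

__all__ = [
    "StudyRecord",
    "CurveFit",
    "DEFAULT_PARAMS",
    "load_study_table",
    "make_study_records",
    "fit_curve",
    "train_test_overlap_report",
]

COHORT_TAGS = ("first-episode", "chronic-mixed", "single-sex", "other")

#: Descriptive reference parameters for the accuracy-vs-N curve.
DEFAULT_PARAMS = {"d0": 2.0, "f": 0.0, "n0": 50.0, "kappa": None}

_BOUNDS = {"d0": (0.05, 6.0), "f": (0.0, 1.0), "n0": (2.0, 500.0), "kappa": (0.0, 1.0)}
_GRIDS = {
    "d0": np.linspace(0.2, 4.0, 16),
    "f": np.linspace(0.0, 1.0, 11),
    "n0": np.geomspace(5.0, 300.0, 12),
    "kappa": np.linspace(0.5, 1.0, 6),
}


@dataclass
class StudyRecord:
    """One published study: group sizes and reported accuracies (percent)."""

    study_id: str
    n_patients: float | None = None
    n_controls: float | None = None
    acc_cv: float | None = None
    acc_test: float | None = None
    cohort_tag: str = "other"
    n_per_group: float | None = None

    def __post_init__(self) -> None:
        if self.acc_cv is None and self.acc_test is None:
            raise DataError(f"study {self.study_id!r}: at least one accuracy required")
        for name in ("acc_cv", "acc_test"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 100.0:
                raise DataError(f"study {self.study_id!r}: {name}={value} out of range [0, 100]")
        for name in ("n_patients", "n_controls"):
            value = getattr(self, name)
            if value is not None and value < 1:
                raise DataError(f"study {self.study_id!r}: {name}={value} must be >= 1")
        if self.cohort_tag not in COHORT_TAGS:
            raise DataError(f"study {self.study_id!r}: unknown cohort_tag {self.cohort_tag!r}")
        if self.n_per_group is None and self.n_patients is not None and self.n_controls is not None:
            # per-group size as the mean of the patient and control counts
            self.n_per_group = 0.5 * (self.n_patients + self.n_controls)


def _cell(row, name):
    value = row.get(name)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return value


def load_study_table(path) -> list[StudyRecord]:
    """Read a study CSV into validated records.

    Expected columns: study_id, n_patients, n_controls, acc_cv, acc_test,
    cohort_tag; missing values blank.  ``n_per_group`` is computed as the
    mean of the patient and control counts when both are present.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty study table: {path}")
        return []
    if "study_id" not in frame.columns:
        raise DataError(f"study table {path} lacks required column 'study_id'")
    if not ("acc_cv" in frame.columns or "acc_test" in frame.columns):
        raise DataError(f"study table {path} lacks accuracy columns")
    if frame.empty:
        warnings.warn(f"empty study table: {path}")
        return []
    records = []
    for i, row in enumerate(frame.to_dict(orient="records")):
        try:
            records.append(
                StudyRecord(
                    study_id=str(row["study_id"]),
                    n_patients=_cell(row, "n_patients"),
                    n_controls=_cell(row, "n_controls"),
                    acc_cv=_cell(row, "acc_cv"),
                    acc_test=_cell(row, "acc_test"),
                    cohort_tag=_cell(row, "cohort_tag") or "other",
                )
            )
        except DataError as exc:
            raise DataError(f"row {i}: {exc}") from exc
    return records


def make_study_records(
    d0: float = 2.0,
    f: float = 0.0,
    n0: float = 50.0,
    n_values=(15, 25, 35, 50, 70, 90, 120, 160, 200, 260, 320, 400),
    kappa: float | None = None,
    jitter: bool = False,
    seed: int | None = None,
) -> list[StudyRecord]:
    """Generate a synthetic study table from the accuracy-vs-N curve.

    With ``jitter`` each accuracy receives normal sampling noise with
    SD = sqrt(acc (100 - acc) / (2 n)) -- the binomial SD of an observed
    accuracy for n subjects per group.
    """
    spec = HeterogeneitySpec(d0=d0, f=f, n0=n0)
    rng = np.random.default_rng(seed)
    records = []
    for n in n_values:
        acc = float(predict_accuracy_curve(spec, n, ceiling_kappa=kappa))
        if jitter:
            acc += rng.normal(0.0, sampling_sd(acc, int(2 * n)))
            acc = float(np.clip(acc, 1.0, 99.9))
        records.append(
            StudyRecord(study_id=f"synthetic_n{n}", n_patients=n, n_controls=n, acc_cv=acc)
        )
    return records


@dataclass
class CurveFit:
    """Result of fitting the heterogeneity curve to study records."""

    params: dict  #: all four parameters, fitted or fixed
    free: tuple  #: names of the fitted parameters
    mode: str  #: "all-points" or "envelope"
    n_points: int
    residuals: np.ndarray  #: acc_observed - acc_predicted per fitted point
    sse: float
    bootstrap_ci: dict = field(default_factory=dict)  #: param -> (low, high)
    n_bootstrap: int = 0

    def to_dict(self) -> dict:
        return {
            "params": {k: v for k, v in self.params.items()},
            "free": list(self.free),
            "mode": self.mode,
            "n_points": self.n_points,
            "sse": self.sse,
            "residual_rms": float(np.sqrt(np.mean(self.residuals**2))) if self.n_points else None,
            "bootstrap_ci": {k: list(v) for k, v in self.bootstrap_ci.items()},
            "n_bootstrap": self.n_bootstrap,
        }


def _predict(params: dict, n: np.ndarray) -> np.ndarray:
    spec = HeterogeneitySpec(d0=params["d0"], f=params["f"], n0=params["n0"])
    return predict_accuracy_curve(spec, n, ceiling_kappa=params.get("kappa"))


def _fast_curve(d0, f, n0, kappa, n: np.ndarray) -> np.ndarray:
    # validation-free inner-loop version of _predict for the optimizer
    h = np.maximum(1.0, n / n0)
    arg = (1.0 + (h - 1.0) * f) / h
    acc = 100.0 * ndtr(d0 * np.sqrt(arg) / 2.0)
    if kappa is not None:
        acc = kappa * acc + 50.0 * (1.0 - kappa)
    return acc


def _points(records, mode: str, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    usable = [
        r for r in records if r.acc_cv is not None and r.n_per_group is not None
    ]
    if not usable:
        raise DataError("no CV accuracies with sample sizes present")
    n = np.array([r.n_per_group for r in usable], dtype=float)
    acc = np.array([r.acc_cv for r in usable], dtype=float)
    if mode == "all-points":
        return n, acc
    if mode != "envelope":
        raise ValueError(f"unknown fit mode: {mode!r}")
    # envelope: the best accuracy per log-spaced sample-size bin
    edges = np.geomspace(n.min(), n.max(), n_bins + 1)
    edges[-1] *= 1.0 + 1e-9
    keep_n, keep_acc = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (n >= lo) & (n < hi)
        if mask.any():
            best = np.argmax(np.where(mask, acc, -np.inf))
            keep_n.append(n[best])
            keep_acc.append(acc[best])
    return np.asarray(keep_n), np.asarray(keep_acc)


def _make_objective(free, fixed, n, acc):
    lo = np.array([_BOUNDS[name][0] for name in free])
    hi = np.array([_BOUNDS[name][1] for name in free])
    span = hi - lo

    def from_unit(u):
        return lo + np.clip(u, 0.0, 1.0) * span

    base = dict(DEFAULT_PARAMS)
    base.update(fixed)

    def objective(u):
        penalty = float(np.sum(np.square(np.maximum(0.0, -u) + np.maximum(0.0, u - 1.0))))
        params = dict(base)
        params.update(zip(free, from_unit(u)))
        resid = _fast_curve(params["d0"], params["f"], params["n0"], params["kappa"], n) - acc
        return float(resid @ resid) + 1e4 * penalty

    return objective, from_unit, lo, span


def _minimize(objective, u0):
    best = minimize(
        objective,
        u0,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000, "maxfev": 6000},
    )
    # one restart guards against premature simplex collapse
    again = minimize(
        objective,
        best.x,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000, "maxfev": 4000},
    )
    return again if again.fun <= best.fun else best


def fit_curve(
    records,
    free: tuple = ("d0", "f", "n0"),
    fixed: dict | None = None,
    mode: str = "all-points",
    n_bins: int = 5,
    n_bootstrap: int = 0,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> CurveFit:
    """Least-squares fit of the accuracy-vs-N curve to study records.

    ``free`` names the parameters to fit (subset of d0, f, n0, kappa); the
    rest are held at ``fixed`` (defaulting to the descriptive reference set
    d0 = 2, f = 0, N0 = 50, no label ceiling).  ``mode`` "all-points" fits
    every CV point; "envelope" fits only the maximum accuracy per
    log-spaced sample-size bin, tracing the upper edge of the point cloud.
    The optimizer is deterministic: a bounded grid search followed by
    Nelder-Mead refinement on unit-scaled parameters.  With
    ``n_bootstrap`` > 0, case-resampling percentile CIs are attached
    (seeded; refits start from the full-data solution).
    """
    free = tuple(free)
    for name in free:
        if name not in _BOUNDS:
            raise ValueError(f"unknown parameter: {name!r}")
    params = dict(DEFAULT_PARAMS)
    if fixed:
        params.update(fixed)
    fixed_full = {k: v for k, v in params.items() if k not in free}
    if "kappa" in free and fixed_full.get("kappa", 0) is None:
        fixed_full.pop("kappa", None)

    n, acc = _points(records, mode, n_bins)
    if n.size < len(free):
        raise DataError(
            f"under-determined fit: {n.size} points for {len(free)} free parameters"
        )

    objective, from_unit, lo, span = _make_objective(free, fixed_full, n, acc)

    # coarse deterministic grid, then multi-start refinement from the best
    # candidates (the d0/N0 ridge of the curve can trap a single start)
    grids = []
    for name in free:
        g = _GRIDS[name]
        grids.append((g - _BOUNDS[name][0]) / (_BOUNDS[name][1] - _BOUNDS[name][0]))
    combos = np.array(list(itertools.product(*grids)))
    values = np.array([objective(u) for u in combos])
    starts = combos[np.argsort(values)[: min(5, len(combos))]]
    result = None
    for u0 in starts:
        candidate = _minimize(objective, u0)
        if result is None or candidate.fun < result.fun:
            result = candidate
    theta = from_unit(result.x)
    fitted = dict(fixed_full)
    fitted.update(zip(free, (float(v) for v in theta)))
    if "kappa" not in fitted:
        fitted["kappa"] = None
    residuals = acc - _predict(fitted, n)

    boot_ci: dict = {}
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)

        # each refit restarts globally (coarse grid + the full-data solution):
        # resampled tables can prefer a different basin of the d0/N0 ridge,
        # and a purely local refit would understate that variability
        coarse = np.array(
            list(
                itertools.product(
                    *(
                        (
                            _GRIDS[name][::2] - _BOUNDS[name][0]
                        )
                        / (_BOUNDS[name][1] - _BOUNDS[name][0])
                        for name in free
                    )
                )
            )
        )

        def refit(n_sub, acc_sub):
            obj_b, from_unit_b, _, _ = _make_objective(free, fixed_full, n_sub, acc_sub)
            values_b = np.array([obj_b(u) for u in coarse])
            best = None
            for u0 in (coarse[int(np.argmin(values_b))], result.x):
                res_b = minimize(
                    obj_b,
                    u0,
                    method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 1000},
                )
                if best is None or res_b.fun < best.fun:
                    best = res_b
            return from_unit_b(best.x)

        draws = np.array(
            [refit(n[idx], acc[idx]) for idx in
             (rng.integers(0, n.size, size=n.size) for _ in range(n_bootstrap))]
        )
        # jackknife estimates for the BCa acceleration constant
        jack = np.array(
            [refit(np.delete(n, i), np.delete(acc, i)) for i in range(n.size)]
        )
        theta_hat = np.array([fitted[name] for name in free], dtype=float)
        for j, name in enumerate(free):
            boot_ci[name] = _bca_interval(draws[:, j], jack[:, j], theta_hat[j], ci_level)

    return CurveFit(
        params=fitted,
        free=free,
        mode=mode,
        n_points=int(n.size),
        residuals=residuals,
        sse=float(residuals @ residuals),
        bootstrap_ci=boot_ci,
        n_bootstrap=n_bootstrap,
    )


def _bca_interval(draws: np.ndarray, jack: np.ndarray, theta_hat: float, level: float):
    """Bias-corrected accelerated (BCa) bootstrap interval.

    Corrects the percentile interval for median bias (z0, from the fraction
    of bootstrap draws below the point estimate) and for skewness of the
    estimator (acceleration a, from the jackknife).  Falls back to the
    plain percentile interval when the correction is degenerate.
    """
    alpha = (1.0 - level) / 2.0
    frac = np.mean(draws < theta_hat)
    if frac <= 0.0 or frac >= 1.0:
        lo, hi = np.percentile(draws, [100 * alpha, 100 * (1 - alpha)])
        return (float(lo), float(hi))
    z0 = norm.ppf(frac)
    diff = jack.mean() - jack
    denom = np.sum(diff**2) ** 1.5
    a = float(np.sum(diff**3) / (6.0 * denom)) if denom > 0 else 0.0
    z = norm.ppf([alpha, 1.0 - alpha])
    adj = norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
    lo, hi = np.percentile(draws, 100.0 * adj)
    return (float(lo), float(hi))


def train_test_overlap_report(records) -> pd.DataFrame:
    """Per-study overlap estimates for records with train and test accuracy.

    Applies both the exact inversion and the 53-point log rule.  Records
    where the test accuracy exceeds the train accuracy get no numeric f (a
    shared-feature fraction cannot exceed 1); they are flagged as sampling
    effects instead.  Estimates from train accuracies outside the 70-90%
    validity band are flagged too.
    """
    rows = []
    for r in records:
        if r.acc_cv is None or r.acc_test is None:
            continue
        note = ""
        f_exact = f_approx = np.nan
        if r.acc_test > r.acc_cv:
            note = "test exceeded train; sampling effect suspected"
        elif r.acc_cv <= 50.0:
            note = "train accuracy at or below chance; f undefined"
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f_exact = estimate_overlap(r.acc_cv, r.acc_test, method="exact")
                f_approx = estimate_overlap(r.acc_cv, r.acc_test, method="log-approx")
            if not 70.0 <= r.acc_cv <= 90.0:
                note = "train accuracy outside 70-90% validity band"
        rows.append(
            {
                "study_id": r.study_id,
                "acc_cv": r.acc_cv,
                "acc_test": r.acc_test,
                "f_exact": f_exact,
                "f_log_approx": f_approx,
                "note": note,
            }
        )
    if not rows:
        raise DataError("no eligible records: need both acc_cv and acc_test")
    return pd.DataFrame(rows)
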