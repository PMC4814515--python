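"""Synthetic petal-structured case-control data and validation experiments.

The generator realizes the petal model literally: features are independent
Gaussians with equal variance in both groups (which makes every closed form
exact in expectation), controls are centered at zero, and a patient of
subgroup h is shifted by +delta on a shared core of ``k_shared`` features
and on subgroup h's own block of ``k_unique`` "petal" features.  The
pairwise overlap between two subgroups' true shift vectors is then exactly

    f = k_shared / (k_shared + k_unique),

and fractional targets are met by giving one extra core feature a scaled
shift.  The homogeneous-subsample effect size of the optimal linear model
is d0 = delta * sqrt(k_shared + k_unique) / sigma with
sigma = sqrt(sigma_biol^2 + sigma_exp^2).

``run_experiment`` trains linear classifiers on replicate samples and pairs
every empirical quantity (CV accuracy, independent-test accuracy, held-out
effect size, weight-vector overlap) with its analytic prediction from the
:mod:`heterogeneity` and :mod:`uncertainty` modules.  Single-fit weight
vectors are shrunk toward noise by estimation error (a factor
~1/sqrt(1 + p / (n_eff d^2))), so the *population-level* closed forms are
validated on the ensemble model obtained by averaging the fitted weight
vectors across replicates, evaluated on a held-out sample; per-replicate
metrics retain the finite-sample behaviour.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .effectsize import GroupScores, compute_effect_size, accuracy_from_effect_size
from .heterogeneity import (
    LinearModel,
    TrainTestOverlap,
    compose_noise,
    train_test_overlap_attenuation,
    weight_overlap,
    within_sample_attenuation,
)
from .uncertainty import LabelQuality, sampling_sd, silver_standard_accuracy

__all__ = [
    "SimulationConfig",
    "SampleData",
    "ExperimentResult",
    "OverlapRecovery",
    "generate_sample",
    "train_linear",
    "cross_val_accuracy",
    "run_experiment",
    "recover_overlap",
]

_CLASSIFIERS = ("regularized-discriminant", "hinge-linear")


@dataclass
class SimulationConfig:
    """Full generative recipe for a heterogeneous case-control experiment.

    Parameters
    ----------
    p
        Feature dimension.
    n_per_group
        Training subjects per group (controls; patients split over subgroups).
    n_subgroups
        Number H of homogeneous patient subgroups in the training population.
    f_target
        Intended pairwise overlap between subgroup shift vectors, in [0, 1].
    d0_target
        Homogeneous-subsample ML effect size; sets ``delta`` when that is
        not given explicitly.
    delta
        Per-feature mean shift of affected features, in units of the total
        within-group feature SD.  Overrides ``d0_target`` when given.
    k_total
        Discriminative features per subgroup (core + petal); the overlap
        target is realized as k_shared = f * k_total, k_unique =
        (1 - f) * k_total, with one fractional core feature if needed.
    sigma_biol, sigma_exp
        SDs of the biological and measurement-noise contributions to each
        feature; composed in quadrature.
    label_flip_train, label_flip_test
        Fractions of training / test labels flipped (silver standard with
        kappa = 1 - 2 * fraction).
    classifier
        "regularized-discriminant" (closed-form, deterministic; default) or
        "hinge-linear" (large-margin SVC, reports n_sv).
    cv_folds
        k for stratified k-fold CV of the training accuracy; 0 disables CV.
    reps
        Monte-Carlo repetitions (independent train/test draws).
    h_prime, t_shared
        Petal structure of the *test* population: H' petals of which
        t_shared are shared with the training population (defaults: same
        population, H' = H, T = H').
    sigma_exp_test
        Measurement-noise SD in the test sample, if different.
    n_test_per_group, n_eval_per_group
        Test-sample and ensemble-evaluation sample sizes per group.
    seed
        Mandatory for any stochastic run; all randomness flows from it via
        a spawned-stream scheme (generation, folds, flips are independent).
    """

    p: int = 200
    n_per_group: int = 500
    n_subgroups: int = 1
    f_target: float = 1.0
    d0_target: float = 2.0
    delta: float | None = None
    k_total: int = 20
    k_shared: int | None = None
    k_unique: int | None = None
    sigma_biol: float = 1.0
    sigma_exp: float = 0.0
    label_flip_train: float = 0.0
    label_flip_test: float = 0.0
    classifier: str = "regularized-discriminant"
    cv_folds: int = 10
    reps: int = 20
    h_prime: int | None = None
    t_shared: int | None = None
    sigma_exp_test: float | None = None
    n_test_per_group: int | None = None
    n_eval_per_group: int = 1000
    seed: int | None = None
    # derived, set in __post_init__
    alpha: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if self.classifier not in _CLASSIFIERS:
            raise ValueError(f"unknown classifier: {self.classifier!r}")
        if self.n_subgroups < 1:
            raise ValueError("n_subgroups must be >= 1")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        for frac in (self.label_flip_train, self.label_flip_test):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("label-flip fractions must lie in [0, 1]")
        if self.k_shared is not None and self.k_unique is not None:
            ks, ku = self.k_shared, self.k_unique
            if ks < 0 or ku < 0 or ks + ku < 1:
                raise ValueError("k_shared/k_unique must be non-negative with a positive sum")
            self.alpha = 0.0
            self.f_target = ks / (ks + ku)
        else:
            if not 0.0 <= self.f_target <= 1.0:
                raise ValueError("f_target must lie in [0, 1]")
            self.k_shared, self.k_unique, self.alpha = _feature_counts(
                self.f_target, self.k_total
            )
        if self.delta is None:
            self.delta = self.d0_target * self.sigma_feature / math.sqrt(self.k_effective)
        else:
            self.d0_target = self.delta * math.sqrt(self.k_effective) / self.sigma_feature
        if self.h_prime is None:
            self.h_prime = self.n_subgroups
        if self.t_shared is None:
            self.t_shared = min(self.n_subgroups, self.h_prime)
        if not 0 <= self.t_shared <= min(self.n_subgroups, self.h_prime):
            raise ValueError("t_shared must satisfy 0 <= T <= min(H, H')")
        if self._n_feature_cols() > self.p:
            raise ValueError(
                f"feature budget exceeded: need {self._n_feature_cols()} columns, have p={self.p}"
            )

    # -- derived geometry ------------------------------------------------
    @property
    def n_core_cols(self) -> int:
        return self.k_shared + (1 if self.alpha > 0.0 else 0)

    def _n_petal_blocks(self) -> int:
        return self.n_subgroups + (self.h_prime - self.t_shared)

    def _n_feature_cols(self) -> int:
        return self.n_core_cols + self.k_unique * self._n_petal_blocks()

    @property
    def sigma_feature(self) -> float:
        """Total per-feature SD, biological + measurement in quadrature."""
        return compose_noise(self.sigma_biol, self.sigma_exp)

    @property
    def k_effective(self) -> float:
        """Squared norm of a subgroup shift vector in units of delta^2."""
        return self.k_shared + self.alpha**2 + self.k_unique

    @property
    def analytic_d0(self) -> float:
        """Effect size of the optimal model on one homogeneous subgroup."""
        return self.delta * math.sqrt(self.k_effective) / self.sigma_feature

    def shift_vector(self, block: int) -> np.ndarray:
        """True mean-shift vector of the subgroup using petal ``block``."""
        v = np.zeros(self.p)
        v[: self.k_shared] = self.delta
        if self.alpha > 0.0:
            v[self.k_shared] = self.alpha * self.delta
        start = self.n_core_cols + block * self.k_unique
        v[start : start + self.k_unique] = self.delta
        return v

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("alpha")
        return json.dumps(d, indent=2)


def _feature_counts(f: float, k_total: int) -> tuple[int, int, float]:
    """Realize an overlap target as (k_shared, k_unique, fractional alpha).

    cos between two subgroup shift vectors = (k_s + alpha^2) / (k_s +
    alpha^2 + k_u) = f exactly.
    """
    if k_total < 1:
        raise ValueError("k_total must be >= 1")
    if f >= 1.0:
        return k_total, 0, 0.0
    if f <= 0.0:
        return 0, k_total, 0.0
    k_unique = max(1, round((1.0 - f) * k_total))
    ks_real = f / (1.0 - f) * k_unique
    k_shared = int(math.floor(ks_real + 1e-12))
    alpha = math.sqrt(max(ks_real - k_shared, 0.0))
    if alpha < 1e-9:
        alpha = 0.0
    return k_shared, k_unique, alpha


@dataclass
class SampleData:
    """A generated case-control sample.

    ``subgroup`` is 0 for controls and 1..H for patient subgroups.
    """

    features: np.ndarray
    labels: np.ndarray
    subgroup: np.ndarray

    @property
    def n(self) -> int:
        return self.labels.size


def _rng_for(config: SimulationConfig, which: str, rng) -> np.random.Generator:
    if rng is not None:
        return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if config.seed is None:
        raise ValueError("seed mandatory for any stochastic run")
    stream = {"train": 0, "test": 1, "eval": 2}[which]
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _subgroup_sizes(n: int, h: int) -> np.ndarray:
    sizes = np.full(h, n // h)
    sizes[: n % h] += 1
    return sizes


def generate_sample(
    config: SimulationConfig, which: str = "train", rng=None
) -> SampleData:
    """Draw a case-control sample from the configured petal populations.

    ``which`` selects the population and size: "train" and "eval" draw from
    the training population (H subgroups using petal blocks 0..H-1); "test"
    draws from the test population (H' subgroups, of which ``t_shared`` use
    training petal blocks and the rest use fresh blocks never seen in
    training) with the test-sample noise level.  Deterministic given the
    configuration seed (or an explicit ``rng``).
    """
    if which not in ("train", "test", "eval"):
        raise ValueError(f"unknown sample kind: {which!r}")
    rng = _rng_for(config, which, rng)
    if which == "train":
        n, h = config.n_per_group, config.n_subgroups
        blocks = list(range(h))
        sigma = config.sigma_feature
    elif which == "eval":
        n, h = config.n_eval_per_group, config.n_subgroups
        blocks = list(range(h))
        sigma = config.sigma_feature
    else:
        n = config.n_test_per_group or config.n_per_group
        h = config.h_prime
        blocks = list(range(config.t_shared)) + [
            config.n_subgroups + j for j in range(h - config.t_shared)
        ]
        sigma_exp = (
            config.sigma_exp_test if config.sigma_exp_test is not None else config.sigma_exp
        )
        sigma = compose_noise(config.sigma_biol, sigma_exp)

    features = rng.normal(0.0, sigma, size=(2 * n, config.p))
    labels = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    subgroup = np.zeros(2 * n, dtype=int)
    start = n
    for idx, (block, size) in enumerate(zip(blocks, _subgroup_sizes(n, h)), start=1):
        features[start : start + size] += config.shift_vector(block)
        subgroup[start : start + size] = idx
        start += size
    return SampleData(features=features, labels=labels, subgroup=subgroup)


def _fit_discriminant(features: np.ndarray, labels: np.ndarray, ridge: float) -> LinearModel:
    x0 = features[labels == 0]
    x1 = features[labels == 1]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("single-class input: need >= 2 subjects per class")
    m0 = x0.mean(axis=0)
    m1 = x1.mean(axis=0)
    s2 = 0.5 * (x0.var(axis=0, ddof=1) + x1.var(axis=0, ddof=1))
    lam = ridge * float(s2.mean()) if s2.mean() > 0 else ridge
    w = (m1 - m0) / (s2 + lam)
    b = -float(w @ (0.5 * (m0 + m1)))
    return LinearModel(weights=w, offset=b)


def _fit_hinge(features: np.ndarray, labels: np.ndarray) -> LinearModel:
    if len(np.unique(labels)) < 2:
        raise ValueError("single-class input: need both classes")
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(features, labels)
    return LinearModel(
        weights=clf.coef_.ravel(),
        offset=float(clf.intercept_[0]),
        n_sv=int(clf.support_.size),
    )


def train_linear(sample, config: SimulationConfig | None = None, *, ridge: float = 1e-3) -> LinearModel:
    """Fit a linear classifier to a sample.

    The default "regularized-discriminant" is the closed-form diagonal
    discriminant w = (mean1 - mean0) / (s^2 + lambda) with a ridge-stabilized
    per-feature variance scaling -- deterministic and a function of the
    sufficient statistics only.  "hinge-linear" fits a large-margin linear
    SVC and reports the support-vector count.
    """
    if hasattr(sample, "features"):
        features, labels = sample.features, sample.labels
    else:
        features, labels = sample
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).ravel()
    kind = config.classifier if config is not None else "regularized-discriminant"
    if kind == "hinge-linear":
        return _fit_hinge(features, labels)
    return _fit_discriminant(features, labels, ridge)


def cross_val_accuracy(
    features: np.ndarray, labels: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> float:
    """Stratified k-fold CV accuracy (percent) of the configured classifier."""
    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    hits = 0
    for train_idx, val_idx in skf.split(features, labels):
        model = train_linear((features[train_idx], labels[train_idx]), config)
        pred = model.decision_values(features[val_idx]) > 0.0
        hits += int(np.sum(pred == labels[val_idx].astype(bool)))
    return 100.0 * hits / labels.size


def _flip_labels(labels: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Flip a fixed fraction of labels (rounded count, random subset)."""
    flipped = labels.copy()
    k = int(round(fraction * labels.size))
    if k:
        idx = rng.choice(labels.size, size=k, replace=False)
        flipped[idx] = 1 - flipped[idx]
    return flipped


@dataclass
class ExperimentResult:
    """Replicate metrics paired with their analytic predictions."""

    config: SimulationConfig
    per_rep: pd.DataFrame  #: columns rep, acc_cv, acc_test, acc_test_clean, d_ml, n_sv
    acc_cv_mean: float
    acc_cv_sd: float
    acc_test_mean: float
    acc_test_sd: float
    acc_test_clean_mean: float
    d_ml_mean: float
    d_ml_sd: float
    d_ml_ensemble: float  #: effect size of the replicate-averaged model
    attenuation_ensemble: float  #: d_ml_ensemble / analytic d0
    w_bar: np.ndarray
    analytic: dict

    def summary(self) -> dict:
        return {
            "acc_cv_mean": self.acc_cv_mean,
            "acc_cv_sd": self.acc_cv_sd,
            "acc_test_mean": self.acc_test_mean,
            "acc_test_sd": self.acc_test_sd,
            "acc_test_clean_mean": self.acc_test_clean_mean,
            "d_ml_mean": self.d_ml_mean,
            "d_ml_sd": self.d_ml_sd,
            "d_ml_ensemble": self.d_ml_ensemble,
            "attenuation_ensemble": self.attenuation_ensemble,
            "analytic": self.analytic,
        }

    def to_json(self, path) -> None:
        record = self.summary()
        record["per_rep"] = self.per_rep.to_dict(orient="list")
        Path(path).write_text(json.dumps(record, indent=2, default=float))

    def to_tidy_csv(self, path) -> None:
        """One row per replicate per metric, plotting-ready."""
        tidy = self.per_rep.melt(id_vars="rep", var_name="metric", value_name="value")
        tidy.to_csv(path, index=False)


def run_experiment(config: SimulationConfig) -> ExperimentResult:
    """Run the full replicate experiment defined by ``config``.

    Per replicate: draw a training sample, optionally flip training labels,
    measure stratified k-fold CV accuracy, fit the classifier, draw an
    independent test sample (its own petal structure if H'/T are set),
    measure test accuracy against observed (possibly flipped) and clean
    labels, and compute the held-out ML effect size.  Afterwards the fitted
    weight vectors are averaged into an ensemble model whose effect size on
    a held-out evaluation sample estimates the population-level attenuation.
    """
    if config.seed is None:
        raise ValueError("seed mandatory for any stochastic run")
    root = np.random.SeedSequence([config.seed, 9])
    rep_seeds = root.spawn(config.reps + 1)
    rows = []
    weights = []
    offsets = []
    for rep in range(config.reps):
        s_train, s_cv, s_test, s_flip_tr, s_flip_te = rep_seeds[rep].spawn(5)
        train = generate_sample(config, "train", np.random.default_rng(s_train))
        labels_obs = (
            _flip_labels(train.labels, config.label_flip_train, np.random.default_rng(s_flip_tr))
            if config.label_flip_train > 0.0
            else train.labels
        )
        acc_cv = (
            cross_val_accuracy(train.features, labels_obs, config, np.random.default_rng(s_cv))
            if config.cv_folds >= 2
            else np.nan
        )
        model = train_linear((train.features, labels_obs), config)
        test = generate_sample(config, "test", np.random.default_rng(s_test))
        decisions = model.decision_values(test.features)
        pred = decisions > 0.0
        acc_clean = 100.0 * float(np.mean(pred == test.labels.astype(bool)))
        test_labels_obs = (
            _flip_labels(test.labels, config.label_flip_test, np.random.default_rng(s_flip_te))
            if config.label_flip_test > 0.0
            else test.labels
        )
        acc_obs = 100.0 * float(np.mean(pred == test_labels_obs.astype(bool)))
        d_rep = compute_effect_size(GroupScores(test.labels, decisions)).d_ml
        weights.append(model.weights)
        offsets.append(model.offset)
        rows.append(
            {
                "rep": rep,
                "acc_cv": acc_cv,
                "acc_test": acc_obs,
                "acc_test_clean": acc_clean,
                "d_ml": d_rep,
                "n_sv": model.n_sv if model.n_sv is not None else np.nan,
            }
        )
    per_rep = pd.DataFrame(rows)

    w_bar = np.mean(np.stack(weights), axis=0)
    b_bar = float(np.mean(offsets))
    ensemble = LinearModel(weights=w_bar, offset=b_bar)
    eval_sample = generate_sample(config, "eval", np.random.default_rng(rep_seeds[-1]))
    d_ens = compute_effect_size(
        GroupScores(eval_sample.labels, ensemble.decision_values(eval_sample.features))
    ).d_ml
    d0 = config.analytic_d0
    attenuation = d_ens / d0 if d0 > 0 else np.nan

    analytic = _analytic_predictions(config)
    return ExperimentResult(
        config=config,
        per_rep=per_rep,
        acc_cv_mean=float(np.nanmean(per_rep["acc_cv"])) if config.cv_folds >= 2 else np.nan,
        acc_cv_sd=(
            float(np.nanstd(per_rep["acc_cv"], ddof=1))
            if config.cv_folds >= 2 and config.reps > 1
            else np.nan
        ),
        acc_test_mean=float(per_rep["acc_test"].mean()),
        acc_test_sd=float(per_rep["acc_test"].std(ddof=1)) if config.reps > 1 else np.nan,
        acc_test_clean_mean=float(per_rep["acc_test_clean"].mean()),
        d_ml_mean=float(per_rep["d_ml"].mean()),
        d_ml_sd=float(per_rep["d_ml"].std(ddof=1)) if config.reps > 1 else np.nan,
        d_ml_ensemble=d_ens,
        attenuation_ensemble=float(attenuation),
        w_bar=w_bar,
        analytic=analytic,
    )


def _analytic_predictions(config: SimulationConfig) -> dict:
    """Closed-form counterparts of the measured quantities."""
    d0 = config.analytic_d0
    h = config.n_subgroups
    f = config.f_target
    atten_within = within_sample_attenuation(f, h)
    d_train = d0 * atten_within
    overlap = TrainTestOverlap(h=h, h_prime=config.h_prime, t=config.t_shared, f=f)
    atten_test = train_test_overlap_attenuation(overlap)
    sigma_train = config.sigma_feature
    sigma_exp_test = (
        config.sigma_exp_test if config.sigma_exp_test is not None else config.sigma_exp
    )
    sigma_test = compose_noise(config.sigma_biol, sigma_exp_test)
    d_test = d0 * atten_test * (sigma_train / sigma_test) if sigma_test > 0 else np.nan
    acc_train = accuracy_from_effect_size(d_train)
    acc_test_clean = accuracy_from_effect_size(d_test)
    kappa_test = 1.0 - 2.0 * config.label_flip_test
    n_test = 2 * (config.n_test_per_group or config.n_per_group)
    return {
        "d0": d0,
        "within_attenuation": atten_within,
        "test_attenuation": atten_test,
        "d_train": d_train,
        "d_test": d_test,
        "acc_cv": float(acc_train),
        "acc_test_clean": float(acc_test_clean),
        "acc_test": silver_standard_accuracy(float(acc_test_clean), LabelQuality(max(kappa_test, 0.0))),
        "sampling_sd_test": sampling_sd(float(acc_test_clean), n_test),
    }


@dataclass
class OverlapRecovery:
    """Recovered weight-vector overlap versus the generative target."""

    f_target: float
    f_hat: float  #: cos theta of the replicate-averaged subgroup models
    f_hat_single_mean: float  #: mean per-replicate cos theta (noise-attenuated)
    per_rep: np.ndarray


def recover_overlap(config: SimulationConfig) -> OverlapRecovery:
    """Estimate f as cos(theta) between models trained on the two subgroups.

    Requires a two-subgroup configuration.  Per replicate, each subgroup is
    sampled as a homogeneous case-control set (its petal plus the shared
    core) and a linear model is fitted; the per-replicate cos theta between
    the two fitted weight vectors is attenuated toward zero by estimation
    noise, so the replicate-averaged weight vectors provide the
    noise-cancelled estimate ``f_hat``.
    """
    if config.n_subgroups != 2:
        raise ValueError("overlap recovery needs a two-subgroup configuration")
    if config.seed is None:
        raise ValueError("seed mandatory for any stochastic run")
    root = np.random.SeedSequence([config.seed, 7])
    singles = []
    sums = [np.zeros(config.p), np.zeros(config.p)]
    for rep_seed in root.spawn(config.reps):
        pair = []
        for block, sub_seed in enumerate(rep_seed.spawn(2)):
            rng = np.random.default_rng(sub_seed)
            n = config.n_per_group
            features = rng.normal(0.0, config.sigma_feature, size=(2 * n, config.p))
            features[n:] += config.shift_vector(block)
            labels = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
            model = train_linear((features, labels), config)
            pair.append(model.weights)
            sums[block] += model.weights
        singles.append(weight_overlap(pair[0], pair[1])[0])
    f_hat = weight_overlap(sums[0], sums[1])[0]
    return OverlapRecovery(
        f_target=config.f_target,
        f_hat=f_hat,
        f_hat_single_mean=float(np.mean(singles)),
        per_rep=np.asarray(singles),
    )
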