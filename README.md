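# mleffect

Effect sizes, sample heterogeneity and uncertainty for binary biomarker
classifiers.

Case-control classification studies — schizophrenia vs. control from
structural MRI being the motivating case — report accuracies anywhere from
chance to 100%, and the best small-sample results routinely fail to
replicate in larger or independent samples.  `mleffect` implements a
compact statistical framework that makes those numbers comparable: a
classifier's quality is summarized by the **machine-learning effect
size**

    d_ML = Δy / σ_y,        acc = Φ(d_ML / 2),

the standardized separation of its two decision-value distributions
(σ_y = √(s₀²/2 + s₁²/2) pooled), and every design factor of a study acts
on the accuracy through d_ML:

| factor | effect |
|---|---|
| within-sample heterogeneity (H subgroups, overlap f) | d → d·√((1+(H−1)f)/H) |
| between-sample heterogeneity (shared fraction f) | d → f·d, Δacc ≈ 53·log₁₀ f points |
| biological variation / measurement noise | d → (σ_y/σ_yT)·d |
| finite test sample N | SD(acc) = √(acc(100−acc)/N) |
| imperfect labels (interclass κ) | acc = κ·acc₀ + (1−κ)/2 |

The package provides the closed-form calculators, a thin `mleffect` CLI, a
synthetic petal-structured data generator with linear-classifier
experiments that validate every closed form empirically, and a fitter for
published accuracy-vs-N study tables (with case-resampling BCa bootstrap
CIs).  The science and numerics are documented in
[docs/methods.md](docs/methods.md).

It is written for methodologists and meta-analysts of biomarker
classification studies: people who want to translate a reported accuracy
into an effect size, predict what a model will do in an independent
sample, or ask whether a drop in accuracy is heterogeneity or just
sampling noise.

## A worked example

A "large" group-level effect is a weak classifier:

```python
>>> from mleffect import accuracy_from_effect_size, qualify_effect_size
>>> float(accuracy_from_effect_size(0.8))   # Cohen-"large" d = 0.8
65.54...                                    # only ~66% correct
>>> qualify_effect_size(0.8)
'modest'
```

Heterogeneity explains the fall of accuracy with sample size.  With a
homogeneous-sample effect size d₀ = 2.0, disjoint subgroup patterns
(f = 0) and homogeneous subsamples of N₀ = 50 per group
(`python examples/accuracy_vs_sample_size.py`):

```
n/2    H_eff   d_ML   accuracy
   25   1.00   2.00     84.1%
   50   1.00   2.00     84.1%
  100   2.00   1.41     76.0%
  150   3.00   1.15     71.8%
  200   4.00   1.00     69.1%
```

— an 84% plateau for small, homogeneous samples, declining below 70%
beyond 150 subjects per group.  The simulation engine checks this algebra
against actual fitted classifiers
(`python examples/simulation_validation.py`):

```
analytic d0 (homogeneous)      = 2.00
predicted attenuation          = 0.707
measured attenuation (ensemble)= 0.667
CV accuracy                    = 72.8 +/- 1.3% (analytic 76.0%)

cos(theta) recovery of f = 0.5: ensemble 0.49, single-fit mean 0.41 (noise-attenuated)
```

Sampling uncertainty and label quality
(`python examples/sampling_uncertainty.py`):

```
true accuracy 80%, N =  50: SD = 5.7 points, 95% range 68.7-91.3%
true accuracy 80%, N = 200: SD = 2.8 points, 95% range 74.3-85.7%
kappa = 0.8 labels mislabel 10% of subjects; a 90% classifier can only show 82%
```

The same calculators from the shell:

```sh
$ mleffect convert --d 0.8
d_ML     = 0.80
accuracy = 66%  (modest)
$ mleffect uncertainty --acc 80 --n 50
accuracy = 80.0%  (N = 50)
sampling SD = 5.7 points
interval (two-sigma) = 68.7-91.3%
$ mleffect predict --d0 2.0 --f 0 --n0 50 --n 150
n/2 =    150  H_eff =  3.00  d_ML = 1.15  accuracy = 71.8%
```

Each script in `examples/` is a short narrative of one capability:
effect-size basics, the accuracy-vs-N curve, sampling uncertainty,
train/test overlap estimation, simulation-based validation, and study
table fitting.

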