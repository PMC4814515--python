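# Methods

## The ML effect size and the accuracy model

A binary classifier reduces each subject's feature vector x to a scalar
decision value y.  Writing y0, y1 for the group means, s0, s1 for the
group sample SDs (n−1 denominator) and σ_y = √(s0²/2 + s1²/2) for the
unweighted pooled SD, the machine-learning effect size is

    d_ML = (y1 − y0) / σ_y.

Under the equal-variance normal model the two output distributions overlap
so that the fraction of subjects on the correct side of the midpoint
threshold — Cohen's non-overlap U2 — is

    acc = Φ(d_ML / 2).

Everything else in the package is bookkeeping around this identity:

* accuracy → effect size: d = 2 Φ⁻¹(acc);
* AUC → effect size: the equal-variance binormal ROC has
  AUC = Φ(d/√2), so d = √2 Φ⁻¹(AUC);
* t statistic: t = d√N (one-sample convention: N measurements of the
  difference) or t = d√N/2 (two equal groups of N/2; the default for
  case-control designs).  Both conventions appear in the applied
  literature, so both are implemented behind an explicit tag.  p-values
  use the standard normal approximation to the t distribution; exact
  small-sample t quantiles are out of scope.
* qualification: because diagnosis demands more than group separation,
  accuracies <60% (d ≈ 0.50) are "small", 60–70% (d = 1.05) "modest",
  70–80% (d = 1.68) "medium", >80% "large".  The stored breakpoint
  d = 0.50 is the conventional printed value; 2 Φ⁻¹(0.60) = 0.5067, and
  the scale validator therefore accepts a 0.02 discrepancy rather than
  silently reconciling the two.

Accuracies are held as percentages at every public interface; the
silver-standard map computes on fractions internally so that (1−κ)/2 is
dimensionally meaningful.

## The petal model of heterogeneity

A heterogeneous patient sample is modeled as H homogeneous subgroups that
share a core of discriminative features; each subgroup adds its own
"petal" of subgroup-specific features, and any two subgroups' discriminative
patterns overlap by a fraction f ∈ [−1, 1] (negative f: features
discriminative in opposite directions).

**Within-sample attenuation.**  Represent each subgroup's ideal model by a
unit-norm weight vector w_i with pairwise overlaps w_i·w_j = f.  A model
trained on the H-fold mixture is their average; its norm obeys
|Σw_i|² = H + H(H−1)f, and each subgroup's separation projects onto the
averaged direction as (1+(H−1)f)/√(H+H(H−1)f).  The effect size of the
mixture model relative to a homogeneous sample is therefore

    A(f, H) = √((1 + (H − 1) f) / H),

which reduces to √((1+f)/2) at H = 2 and to 1 at H = 1 or f = 1.  H may
be non-integer: continuous sources of heterogeneity (illness duration,
age) are folded into a real-valued H.

**Between-sample attenuation.**  Applying a trained linear model to an
independent population that shares only a fraction f of discriminative
features scales the separation strength, and hence d_ML, by f outright.

**Train/test petal overlap.**  When the test population itself consists of
H′ petals of which T are shared with the training population, the shared
petals project as (1+(H−1)f)/√(H+H(H−1)f) and the unshared ones as
Hf/√(H+H(H−1)f); the expected test attenuation is the H′-petal mixture of
the two.  At H′ = T = H this reduces exactly to A(f, H) (testing the model
on its own population), and at f = 0, T = 0 it vanishes: nothing
transfers.  T counts discrete petals and stays integer.

**Log rules.**  On the accuracy scale the two attenuations are
approximated by Δacc ≈ 53 · log10(f) points (between samples) and
Δacc ≈ 26 · log10((1+f)/2) points (two-subgroup mixing).  Both are tangent
approximations of the Φ model in the neighbourhood of ~80% accuracy.
Their advertised validity band is a train accuracy of 70–90%; our grid
evaluation shows the 53-point rule stays within 2 accuracy points of the
exact Φ drop only while the *test* accuracy also remains in that band —
at (f = 0.6, train = 70%) the test accuracy falls to 62% and the rule
overshoots the exact drop by ~4 points.  The package computes the rules
anywhere they are defined, warns outside the band, and its property tests
assert the 2-point agreement on the both-accuracies-in-band region where
it actually holds.

**Noise.**  Biological variability and measurement noise act identically
on the model output: σ_y² = σ_BIOL² + σ_EXP².  A test sample with output
spread σ_yT rescales the effect size by σ_y/σ_yT, so doubled test noise
acts like a 50% feature overlap.

**Observability of f.**  For linear models y = wᵀx the overlap equals the
cosine of the angle between weight vectors, f = cos θ = ŵ1·ŵ2, which the
package computes from fitted or file-loaded weight vectors.  From a
train/test accuracy pair, f is estimated exactly as
Φ⁻¹(acc_test/100)/Φ⁻¹(acc_train/100) or approximately as
10^((acc_test−acc_train)/53).

**The accuracy-vs-N curve.**  Identifying H with sample size through
H_eff = max(1, n/N0) — below the homogeneous-subsample size N0 the sample
is taken to be homogeneous, giving a plateau — yields

    acc(n) = 100 Φ(d0 A(f, H_eff) / 2),

optionally passed through the silver-standard ceiling.  The reference
parameter set (d0 = 2.00, f = 0, N0 = 50) is a descriptive default, not a
rigorous estimate.  Whether n counts subjects per group or in total is a
convention; the package uses per group throughout.

## Sampling uncertainty and label quality

An observed accuracy on N test subjects is binomial; the normal
approximation has SD = √(acc(100−acc)/N) points.  The default interval is
acc ± 2 SD (a "two-sigma" convention; ±1.96 is available), which at 80%
and N = 200 gives 74.3–85.7%.  For n ≤ 30 the package exposes the exact
binomial coverage of that interval as a comparison oracle; at 60–80%
accuracy and n ≥ 20 the two-sigma interval keeps ≥ 90% exact coverage.
For SVMs, only the support vectors move the separating hyperplane under
leave-one-out perturbations, so N_SV may replace N as a heuristic for the
cross-validation spread.

Expert labels with interclass kappa κ mislabel (1−κ)/2 of subjects; a
classifier with true accuracy acc0 then *shows*

    acc = κ acc0 + (1 − κ)/2   (fractions),

an affine map with fixed point 50% that caps observable accuracy.  Only
this test-phase map has a closed form; the additional effect of label
error on model building is exercised empirically in the simulation engine
via training-label flips.

## The synthetic-data generator

Features are independent Gaussians with equal variance
σ² = σ_BIOL² + σ_EXP² in both groups — the distributional setting in which
every closed form above is exact in expectation.  Controls are centred at
zero; a patient of subgroup h is shifted by +δ on k_shared core features
and on subgroup h's k_unique petal features (disjoint blocks).  The
overlap between subgroup shift vectors is then exactly
f = k_shared/(k_shared + k_unique); fractional targets are met by giving
one extra core feature a shift αδ with α² chosen so the cosine is exact.
Defaults: p = 200 features, k_total = 20 discriminative features per
subgroup, σ_BIOL = 1, σ_EXP = 0, n = 500 per group, and δ set from the
target homogeneous effect size d0 = 2.0 via d0 = δ√k_total/σ — the
regime of the strongest published structural-imaging case-control
classifiers (≈84% homogeneous accuracy), which is also where the
attenuation predictions are most informative.

A test population may differ from the training population in its petal
structure (H′ petals, T shared) and in measurement noise.  Label flips
emulate silver-standard labels on either side.  All randomness derives
from one seed through a spawned-stream scheme (per replicate: generation,
CV folds, test draw, train and test flips), so identical configurations
are bit-identical and sub-experiments are independently reproducible.

**Classifiers.**  The default is a closed-form diagonal ("regularized")
discriminant, w = (m1 − m0)/(s² + λ) with λ a small ridge on the pooled
per-feature variances — deterministic, a function of sufficient
statistics, and exactly the estimator whose population limit the petal
algebra describes.  A hinge-loss linear SVC is available to exercise the
support-vector count; it is not the default because its solution depends
on the regularization path and contributes nothing further to the
closed-form checks.

**Why ensemble validation.**  A single fitted weight vector is the true
direction plus estimation noise of per-feature variance σ²(1/n0 + 1/n1);
at p = 200 and n = 500 per group this shrinks the held-out effect size by
a factor ≈ 1/√(1 + p/(250 d²)) — about 0.75 at d = 1.  Finite-sample
metrics (per-replicate CV and test accuracy, held-out d_ML) are reported
as such, but the *closed forms describe the population model*, so the
validation experiments average the fitted weight vectors across the
independent replicates (the noise cancels in proportion to 1/reps) and
measure the ensemble model's d_ML on a held-out evaluation sample.  With
20 replicates the residual shrinkage is below 0.01 and the measured
attenuation lands within ±0.02 of A(f, H) across f ∈ {0, ½, 1} ×
H ∈ {1, 2, 4}.  The same logic applies to overlap recovery: the cosine of
two single fits is attenuated toward zero by the product of the two
vectors' noise factors (≈ 0.83 f at these sizes, as the per-replicate
numbers show), while the cosine of the replicate-averaged vectors
recovers f to within ±0.02.  Disattenuation by averaging is a design
choice made once; the per-replicate, noise-attenuated estimates are
always reported alongside.

What the generator does **not** emulate: correlated (spatially smooth)
features, unequal group covariances, scanner/site batch effects,
systematic sensitivity/specificity asymmetries, non-linear decision
boundaries, and publication selection.  Passing tests therefore validate
the closed-form algebra under its own assumptions — they do not certify
that real neuroimaging samples obey independent-Gaussian feature models.

## Curve fitting and the bootstrap

`fit_curve` least-squares fits acc(n) to study tables.  The reference
parameter set is deliberately shipped as a *fixture* default — the curve
is a descriptive envelope of study results, and a rigorous fit is
optional and clearly labelled.  Two point sets are supported: every CV
study ("all-points") or the maximum accuracy per log-spaced sample-size
bin ("envelope", 5 bins by default; the bin count is configurable since
no binning rule is canonical).

Numerics: parameters are unit-scaled to their bounds
(d0 ∈ [0.05, 6], f ∈ [0, 1], N0 ∈ [2, 500], κ ∈ [0, 1]); a coarse
deterministic grid locates candidate basins — the curve has a d0·√N0
ridge (on the declining branch only d0²N0 and f are identified; the
plateau disambiguates) that traps single starts — and Nelder–Mead refines
the best five candidates.  Noiseless self-generated tables are recovered
to machine precision.  Fitted f is restricted to [0, 1]: a shared-feature
*fraction* cannot exceed one, which is also why a test accuracy above the
train accuracy yields a flagged qualitative result ("sampling effect
suspected"), never f > 1.

Bootstrap uncertainty uses case resampling of study records (200
resamples by default, seeded).  Each resample is refit with a global
restart (coarse grid plus the full-data solution) because resampled
tables can legitimately prefer the other basin of the ridge, and a purely
local refit would understate that variability.  Intervals are BCa
(bias-corrected accelerated, jackknife acceleration): the N0 estimator is
right-skewed and median-biased on noisy tables, and plain percentile
intervals undercover there.  In the package's own calibration experiment
— tables of 38 studies spanning 15–198 subjects per group, the size and
range of the published literature the curve describes, jittered with
binomial sampling noise √(acc(100−acc)/(2n)) — the 95% BCa intervals
cover the generating (d0, f, N0) in 19, 18 and 18 of 20 seeded
replicates respectively.

## Problem sizes

The validation experiments run at p = 200, n = 500 per group, 20
replicates (attenuation and overlap grids), n = 100–500 per group for the
calibration checks, and 20 × (1 + 200) curve fits for the bootstrap
calibration — sizes chosen so that Monte-Carlo error is comfortably
inside the tolerances being asserted while the full suite stays in the
minutes range on a single CPU.

## Known limitations

* The Φ(d/2) accuracy model assumes symmetric, equal-variance,
  about-normal classifier outputs with the threshold at the midpoint;
  voting-style outputs violate it (use the 2 Φ⁻¹(acc) route instead).
* The petal algebra assumes equal-strength, equally-overlapping
  subgroups; real heterogeneity is neither symmetric nor discrete.
* The log rules are tangent approximations — see above for the region
  where the 2-point agreement genuinely holds.
* Multi-class and continuous-outcome effect sizes, non-linear
  classifiers, Gaussian-process models and systematic scanner bias are
  out of scope.
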