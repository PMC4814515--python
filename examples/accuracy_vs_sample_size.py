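"""The accuracy-vs-sample-size curve under the petal heterogeneity model.

With a homogeneous-sample effect size d0 = 2.0, no shared core between
subgroups (f = 0) and homogeneous subsamples of N0 = 50 per group, the
expected cross-validation accuracy plateaus at Phi(1) = 84% for small
samples and declines as larger samples mix in more heterogeneity.
"""

from mleffect import HeterogeneitySpec, accuracy_curve

spec = HeterogeneitySpec(d0=2.0, f=0.0, n0=50.0)
print("n/2    H_eff   d_ML   accuracy")
for point in accuracy_curve(spec, [25, 50, 75, 100, 150, 200, 300]):
    print(
        f"{point['n_per_group']:5.0f} {point['H_eff']:6.2f} "
        f"{point['d_ml']:6.2f} {point['accuracy_pct']:8.1f}%"
    )
print("\nThe decline below 70% beyond n/2 = 150 mirrors the fall in")
print("published case-control classifier accuracies with sample size.")
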