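"""Monte-Carlo validation of the heterogeneity attenuation closed form.

Generates petal-structured case-control data (two patient subgroups with
no shared discriminative core), trains linear classifiers on replicate
samples, and compares the measured effect-size attenuation with the
closed form sqrt((1 + (H - 1) f) / H) = sqrt(1/2) at H = 2, f = 0.
"""

from mleffect import SimulationConfig, recover_overlap, run_experiment

config = SimulationConfig(
    p=200, n_per_group=500, n_subgroups=2, f_target=0.0, d0_target=2.0,
    cv_folds=10, reps=10, seed=42,
)
result = run_experiment(config)

print(f"analytic d0 (homogeneous)      = {result.analytic['d0']:.2f}")
print(f"predicted attenuation          = {result.analytic['within_attenuation']:.3f}")
print(f"measured attenuation (ensemble)= {result.attenuation_ensemble:.3f}")
print(f"CV accuracy                    = {result.acc_cv_mean:.1f} "
      f"+/- {result.acc_cv_sd:.1f}% (analytic {result.analytic['acc_cv']:.1f}%)")

recovery = recover_overlap(SimulationConfig(
    p=200, n_per_group=500, n_subgroups=2, f_target=0.5, reps=10, seed=43,
))
print(f"\ncos(theta) recovery of f = 0.5: ensemble {recovery.f_hat:.2f}, "
      f"single-fit mean {recovery.f_hat_single_mean:.2f} (noise-attenuated)")
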