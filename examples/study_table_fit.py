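"""Fitting the heterogeneity curve to a study table and reading overlaps.

Builds a synthetic table of study accuracies from known parameters,
refits them, and runs the train/test overlap report on the bundled
example table of worked literature numbers.
"""

from mleffect import (
    example_studies_path,
    fit_curve,
    load_study_table,
    make_study_records,
    train_test_overlap_report,
)

# self-consistency: noiseless records regenerate their parameters
records = make_study_records(d0=2.0, f=0.3, n0=50.0)
fit = fit_curve(records, free=("d0", "f", "n0"))
print("noiseless fit:", {k: round(v, 3) for k, v in fit.params.items() if v is not None})

# jittered records with bootstrap confidence intervals
noisy = make_study_records(d0=2.0, f=0.3, n0=50.0, jitter=True, seed=1)
fit = fit_curve(noisy, free=("d0", "f", "n0"), n_bootstrap=200, seed=2)
for name in fit.free:
    lo, hi = fit.bootstrap_ci[name]
    print(f"{name}: {fit.params[name]:.3g}  95% BCa CI [{lo:.3g}, {hi:.3g}]")

# worked literature numbers: the train/test overlap report
print()
print(train_test_overlap_report(load_study_table(example_studies_path())).to_string(index=False))
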