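"""Sampling variability of an observed accuracy, and label-quality ceilings.

An accuracy measured on N test subjects is a binomial proportion; its
spread shrinks only as 1/sqrt(N).  Imperfect expert labels (interclass
kappa < 1) further cap what any classifier can appear to achieve.
"""

from mleffect import (
    LabelQuality,
    estimate_accuracy,
    mislabel_fraction,
    silver_standard_accuracy,
    sv_based_sd,
    sv_fraction,
)

for n in (50, 200):
    est = estimate_accuracy(80.0, n)
    print(
        f"true accuracy 80%, N = {n:3d}: SD = {est.sd:.1f} points, "
        f"95% range {est.ci_low:.1f}-{est.ci_high:.1f}%"
    )

quality = LabelQuality(kappa=0.8)
print(
    f"\nkappa = 0.8 labels mislabel {mislabel_fraction(quality):.0%} of subjects;"
    f" a 90% classifier can only show {silver_standard_accuracy(90.0, quality):.0f}%"
)

print(
    f"\nSVM heuristic: 257 support vectors of 294 subjects "
    f"({sv_fraction(257, 294):.0f}%) -> CV spread "
    f"~{sv_based_sd(80.0, 257):.1f} points at 80% accuracy"
)
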