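"""Compute a machine-learning effect size from classifier decision values.

Simulates the outputs of a binary biomarker classifier for 80 controls and
80 patients, computes d_ML = delta_y / sigma_y, and converts it to the
expected classification accuracy Phi(d_ML / 2) and a qualification label.
"""

import numpy as np

from mleffect import (
    GroupScores,
    accuracy_from_effect_size,
    compute_effect_size,
    effect_size_from_auc,
    qualify_effect_size,
)

rng = np.random.default_rng(0)
controls = rng.normal(-0.8, 1.0, 80)  # decision values y for healthy controls
patients = rng.normal(+0.8, 1.0, 80)  # population separation d = 1.6

result = compute_effect_size(GroupScores.from_groups(controls, patients))
print(f"separation strength delta_y = {result.delta_y:.3f}")
print(f"pooled output SD sigma_y    = {result.sigma_y:.3f}")
print(f"ML effect size d_ML         = {result.d_ml:.2f}")
print(f"expected accuracy           = {result.accuracy_pct:.1f}%")
print(f"qualification               = {qualify_effect_size(result.d_ml)}")

# a 'large' group-level effect of d = 0.8 is only a modest classifier:
print(f"\nd = 0.8 classifies only {float(accuracy_from_effect_size(0.8)):.0f}% correctly")
# and an AUC of 0.90 corresponds to
print(f"AUC 0.90 corresponds to d_ML = {float(effect_size_from_auc(0.9)):.2f}")
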