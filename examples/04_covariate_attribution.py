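"""Attribute eta to demographics with boosted trees and Shapley values.

A cohort is planted with a dominant ego-network-size effect on eta (plus
small species and sex effects).  The boosted-tree model is interrogated for
global importance, per-ego Shapley attributions and a partial-dependence
curve for ego-network size.
"""

import numpy as np

import socialcircles as sc
from socialcircles.features import FEATURES
from socialcircles.synth import DEFAULT_COEFFICIENTS

coeffs = {k: 0.0 for k in DEFAULT_COEFFICIENTS}
coeffs.update(intercept=0.5, ego_size=0.3, species=0.2, sex=-0.1)
cfg = sc.SyntheticConfig(
    n_groups=12, group_size_range=(8, 28), seed=3,
    coefficients=coeffs, noise_sd=0.3, integer_weights=False,
)
cohort = sc.generate_cohort(cfg)
est = cohort.truth.rename(columns={"eta_true": "eta", "L_true": "L"})
table = sc.build_feature_table(est[["ego_id", "eta", "L", "group_size"]], cohort.metadata)

result = sc.attribution_analysis(table, seed=3)

print("global importance (normalized total gain):")
for f, v in sorted(result.global_importance.items(), key=lambda kv: -kv[1]):
    print(f"  {f:<14} {v:.3f}")

mean_abs = {f: float(np.abs(result.shap_matrix[f]).mean()) for f in FEATURES}
top = max(mean_abs, key=mean_abs.get)
print(f"\nlargest mean |Shapley attribution|: {top} ({mean_abs[top]:.3f})")

curve = result.pdp_curves["ego_size"]
print("\npartial dependence of eta on ego-network size (others at median/mode):")
print(f"  L = {curve['ego_size'].iloc[0]:.0f} -> eta_hat = {curve['prediction'].iloc[0]:.2f}")
print(f"  L = {curve['ego_size'].iloc[-1]:.0f} -> eta_hat = {curve['prediction'].iloc[-1]:.2f}")
# ego_size dominates both views and the PDP rises: more grooming partners,
# more stratified resource allocation, exactly as planted.
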