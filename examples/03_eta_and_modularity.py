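"""Group-level association between mean eta and network modularity.

Six groups are planted with mean eta 0.5, 3 and 6 (two groups each) and a
two-block community structure whose strong ties sit within blocks.  Groups
whose members stratify their grooming more (higher eta) concentrate more
weight inside the blocks, so detected modularity rises with mean eta.
"""

import numpy as np
from scipy.stats import spearmanr

import socialcircles as sc

levels = (0.5, 3.0, 6.0)
means = tuple(np.repeat(levels, 2))
cfg = sc.SyntheticConfig(
    n_groups=6, group_size_range=(10, 14), seed=11,
    group_eta_means=means, block_structure=True,
    block_within_ratio=tuple(1.0 + m for m in means),
    noise_sd=0.3, integer_weights=False,
    coefficients={k: 0.0 for k in sc.synth.DEFAULT_COEFFICIENTS},
)
cohort = sc.generate_cohort(cfg)

records = [
    sc.InteractionRecord(r.group_id, r.actor_id, r.receiver_id, float(r.weight))
    for r in cohort.interactions.itertuples(index=False)
]
meta = [
    sc.IndividualMeta(m.individual_id, m.group_id, m.species, m.sex, float(m.age), m.habitat)
    for m in cohort.metadata.itertuples(index=False)
]
groups = sc.build_group_networks(records, meta)
retained, _ = sc.apply_filters(groups)
fits: dict[str, list] = {}
for grp, tw in retained:
    fits.setdefault(grp.group_id, []).append(sc.fit_ego(tw))

rows = sc.group_structure_table(groups, fits, seed=11)
print(f"{'group':>6} {'planted':>8} {'mean eta':>9} {'Q':>7}")
for planted, row in zip(means, rows):
    print(f"{row.group_id:>6} {planted:>8.1f} {row.mean_eta:>9.2f} {row.q:>7.3f}")
rho = spearmanr([r.mean_eta for r in rows], [r.q for r in rows]).statistic
print(f"\nSpearman rank correlation (mean eta vs Q): {rho:.2f}")
# A positive correlation: more stratified grooming -> more modular groups.
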