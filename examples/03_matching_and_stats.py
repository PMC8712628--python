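"""The statistical toolbox: power analysis, matching, and robust regression.

Mirrors the study's analysis order on synthetic metadata:

1. a-priori sample size for a two-sample t-test (d = 0.8, one-tailed),
2. coarsened exact matching (CEM) on the intelligence covariate with
   Sturges-rule bins and the L1 imbalance diagnostic,
3. a CEM-weighted group regression of a toy outcome, and
4. an HC1-robust symptom-severity regression with Bonferroni control.

Run with: python examples/03_matching_and_stats.py
"""

import numpy as np

from plinet import (
    CohortEffectSpec,
    bonferroni,
    cem_match,
    generate_participants,
    records_to_frame,
    required_sample_size,
    robust_regression,
    weighted_group_regression,
)

# --- 1. how many subjects does a d = 0.8 effect need? -------------------
n_one = required_sample_size(0.8, alpha=0.05, power=0.8, tail="one")
n_two = required_sample_size(0.8, alpha=0.05, power=0.8, tail="two")
print(f"required n/group for d=0.8, alpha=0.05, power=0.8: "
      f"{n_one} (one-tailed), {n_two} (two-tailed)")

# --- 2. a cohort with a planted intelligence-score imbalance ------------
rng = np.random.default_rng(0)
spec = CohortEffectSpec(n_group_a=20, n_group_b=25, mps_shift=15.3)
records, _ = generate_participants(spec, rng)
meta = records_to_frame(records)

cem = cem_match(meta, match_var="mps")
print()
print(f"CEM on MPS: L1 imbalance {cem.l1_before:.3f} -> {cem.l1_after:.3f}")
print(f"matched {cem.n_matched_treated} ASD-like / {cem.n_matched_control} TD-like "
      f"across {len(cem.strata)} strata")

# --- 3. weighted group regression on a toy outcome ----------------------
# outcome: a noisy score that is genuinely lower in the ASD-like group
group = (meta["group"] == "ASD-like").astype(float).to_numpy()
outcome = 2.0 - 0.4 * group + rng.normal(0, 0.25, len(meta))
weights = meta["subject_id"].map(cem.weights).fillna(0.0).to_numpy()
fit = weighted_group_regression(outcome, group, weights)
print()
print(f"CEM-weighted group coefficient: {fit.coefficients['group']:+.3f} "
      f"(p = {fit.p_values['group']:.4f}, n = {fit.n_obs} weighted subjects)")

# --- 4. robust symptom regressions with Bonferroni control --------------
asd = meta[meta["group"] == "ASD-like"]
outcome_asd = 1.8 - 0.012 * asd["srs_t"].to_numpy() + rng.normal(0, 0.1, len(asd))
scales = ["srs_awa", "srs_cog", "srs_com", "srs_mot", "srs_man"]
pvals = []
print()
print("HC1-robust regressions of the outcome on the five SRS sub-scales:")
for scale in scales:
    f = robust_regression(outcome_asd, asd[scale].to_numpy(), x_name=scale)
    pvals.append(f.p_values[scale])
    print(f"  {scale}: slope {f.coefficients[scale]:+.4f}, p = {pvals[-1]:.4f}")
decisions = bonferroni(pvals, m=5)
print(f"significant after Bonferroni (alpha/5 = 0.01): "
      f"{[s for s, d in zip(scales, decisions) if d] or 'none'}")
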