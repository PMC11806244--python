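"""A small replicated simulation study with filtering and summaries.

Compares ITT, per-protocol and IPW across 300 replications of scenarios A1
(no confounding) and A4b (unmeasured confounding with arm-opposite
selection) at the boundary null: the truth (-0.3) equals the margin, so the
NI declaration rate is the type-I error and should sit near 2.5% when an
estimator's assumptions hold.
"""

import nicomply as nc
from nicomply.simstudy import filter_replications, run_study, summarize

N_REPS = 300  # keep the example quick; use ~2000 for stable rates

for label in ("A1", "A4b"):
    cfg = nc.preset(label)
    records = run_study(cfg, ["itt", "pp", "ipw"], n_reps=N_REPS,
                        master_seed=1, margin=-0.3)
    records = filter_replications(records)
    summary = summarize(records, truth=nc.true_hypothetical_estimand(cfg),
                        margin=-0.3)
    cols = ["n_reps_used", "mean_estimate", "bias", "mc_se_bias",
            "empirical_se", "ni_rate_pct", "precision_increase_vs_itt_pct"]
    print(f"\nscenario {label} (truth -0.3, margin -0.3):")
    print(summary.to_frame()[cols].round(4).to_string())

print(
    "\nUnder A1 the complier-based estimators are unbiased with type-I near "
    "2.5% (ITT is anti-conservative because 30% non-compliance dilutes its "
    "target towards zero); under A4b the unmeasured selection biases PP and "
    "IPW upwards and inflates their type-I error."
)
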