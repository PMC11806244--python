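"""Fit all five estimators of the hypothetical treatment effect on one trial.

The trial comes from scenario A4a (compliance driven by an unobserved
covariate): per-protocol and IPW can only adjust for the observed X, so on
average they are biased here, while the instrumental-variable approaches are
not (given a well-centered prior for the Bayesian variant).  On a single
trial all five simply produce point estimates and intervals around the true
value of -0.3.
"""

import nicomply as nc

cfg = nc.preset("A4a")
trial = nc.generate_trial(cfg, seed=12)
margin = -0.3

results = [
    nc.fit_itt(trial),
    nc.fit_pp(trial),
    nc.fit_ipw(trial),
    nc.fit_iv_interaction(trial),
    nc.fit_iv_bayes(trial, nc.make_prior(cfg.beta_c0, "well", "precise"), seed=1),
]

print(f"true hypothetical estimand: {nc.true_hypothetical_estimand(cfg)}")
print(f"{'method':16s} {'estimate':>9s} {'se':>7s} {'95% interval':>18s} {'NI?':>4s}")
for res in results:
    dec = nc.declare_noninferiority(res, margin=margin)
    print(
        f"{res.method:16s} {res.estimate:9.3f} {res.se:7.3f} "
        f"[{res.interval_lower:7.3f}, {res.interval_upper:6.3f}] "
        f"{'yes' if dec.declared else 'no':>4s}"
    )
print(
    "\nNI is declared when the lower interval limit exceeds the margin "
    f"({margin}); with the truth exactly on the margin this should happen "
    "in only ~2.5% of trials for a well-calibrated estimator."
)
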