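"""Prior sensitivity of the Bayesian IV estimator on a single trial.

The informative prior sits on the effect of *receiving the standard
treatment versus nothing* (beta_c0), the quantity historical
placebo-controlled evidence usually informs.  The four grid priors cross
centering (well vs. displaced by +0.5) with precision (sd 1 vs. sd 10).
When the two arms have different compliance rates, the posterior contrast
inherits a bias proportional to the prior's mis-centering times the
relative compliance difference; at equal compliance rates the contrast is
insensitive to the prior.
"""

import nicomply as nc

for scenario in ("A4a", "A4a_eq"):
    # a large trial so the sample compliance rates sit close to their
    # population values and the equal-compliance robustness is visible
    cfg = nc.preset(scenario).replace(n=2000)
    trial = nc.generate_trial(cfg, seed=3)
    rates = (trial.C[trial.Z == 0].mean(), trial.C[trial.Z == 1].mean())
    print(f"\nscenario {scenario}: arm compliance rates "
          f"{rates[0]:.2f} / {rates[1]:.2f}")
    for centering in ("well", "mis"):
        for precision in ("precise", "vague"):
            prior = nc.make_prior(cfg.beta_c0, centering, precision)
            res = nc.fit_iv_bayes(trial, prior, variant="plugin", chains=2,
                                  draws=1500, warmup=300, seed=11)
            print(f"  {prior.label:22s} estimate {res.estimate:7.3f} "
                  f"(posterior sd {res.se:.3f})")
print(
    "\nMis-centering shifts the estimate when arm compliance rates differ "
    "(A4a) but not when they are equal (A4a_eq)."
)
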