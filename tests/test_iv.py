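"""Instrumental-variable estimators against independent oracles.

The 2SLS implementation is checked against a direct moment-equation solve
(the model is just-identified, so beta = (V'W)^-1 V'y with instrument block
V and regressor block W) and against the statsmodels sandbox IV2SLS as an
independent library cross-check.  The Bayesian IV is checked against the
degenerate-prior closed form and the identified full-compliance limit.
"""

import numpy as np
import pytest

from nicomply.bayes import PriorSpec, fit_iv_bayes, make_prior
from nicomply.datagen import generate_trial, preset
from nicomply.estimators import IdentifiabilityError, fit_iv_interaction

from conftest import make_dataset


def moment_equation_2sls(data):
    """Independent oracle: solve the just-identified instrument moment
    equations directly."""
    ones = np.ones(data.n)
    W = np.column_stack([ones, data.X, data.R0, data.R1]).astype(float)
    V = np.column_stack([ones, data.X, data.Z, data.Z * data.X]).astype(float)
    beta = np.linalg.solve(V.T @ W, V.T @ data.Y)
    return beta[3] - beta[2]


def random_trial(rng, n):
    """Random small instance with instrument-relevant compliance."""
    Z = rng.integers(0, 2, n)
    X = rng.integers(0, 2, n)
    # X-dependent compliance with opposite slopes by arm
    p = np.where(Z == 1, 0.55 + 0.35 * X, 0.9 - 0.45 * X)
    C = (rng.random(n) < p).astype(int)
    R0, R1 = (1 - Z) * C, Z * C
    Y = 0.4 * R0 + 0.1 * R1 + 0.5 * X + rng.normal(0, 1, n)
    return make_dataset(Z=Z, C=C, X=X, Y=Y)


class Test2SLS:
    def test_matches_moment_equation_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 25:
            n = int(rng.integers(20, 201))
            d = random_trial(rng, n)
            try:
                res = fit_iv_interaction(d)
            except (IdentifiabilityError, ValueError):
                continue  # degenerate draw (empty arm/cell)
            assert res.estimate == pytest.approx(moment_equation_2sls(d), abs=1e-8)
            checked += 1

    def test_sixteen_row_fixture_matches_oracle(self, sixteen_row_2sls):
        res = fit_iv_interaction(sixteen_row_2sls)
        assert res.estimate == pytest.approx(
            moment_equation_2sls(sixteen_row_2sls), abs=1e-8
        )
        assert res.se > 0

    def test_matches_statsmodels_iv2sls(self, sixteen_row_2sls):
        from statsmodels.sandbox.regression.gmm import IV2SLS

        d = sixteen_row_2sls
        ones = np.ones(d.n)
        W = np.column_stack([ones, d.X, d.R0, d.R1]).astype(float)
        V = np.column_stack([ones, d.X, d.Z, d.Z * d.X]).astype(float)
        sm_res = IV2SLS(d.Y, W, instrument=V).fit()
        res = fit_iv_interaction(d)
        assert res.estimate == pytest.approx(
            sm_res.params[3] - sm_res.params[2], abs=1e-8
        )

    def test_full_compliance_raises_identifiability_error(
        self, full_compliance_trial
    ):
        with pytest.raises(IdentifiabilityError, match="proportional"):
            fit_iv_interaction(full_compliance_trial)

    def test_constant_covariate_raises(self):
        d = make_dataset(Z=[0, 0, 1, 1], C=[1, 0, 1, 1], X=[0, 0, 0, 0],
                         Y=np.arange(4.0))
        with pytest.raises(IdentifiabilityError):
            fit_iv_interaction(d)

    def test_noiseless_identification_recovers_receipt_contrast(self):
        """Arm 0 fully compliant, arm-1 compliance varying with X, noiseless
        outcome: 2SLS recovers beta_c1 - beta_c0 exactly."""
        rng = np.random.default_rng(5)
        n = 200
        Z = np.repeat([0, 1], n // 2)
        X = np.tile([0, 1], n // 2)
        C = np.where(Z == 0, 1, np.where(X == 1, 1, rng.integers(0, 2, n)))
        R0, R1 = (1 - Z) * C, Z * C
        beta_c0, beta_c1 = 0.5, 0.2
        Y = 0.1 + beta_c0 * R0 + beta_c1 * R1 + 0.5 * X
        d = make_dataset(Z=Z, C=C, X=X, Y=Y)
        res = fit_iv_interaction(d)
        assert res.estimate == pytest.approx(beta_c1 - beta_c0, abs=1e-8)

    def test_stage1_predictions_vanish_in_opposite_arm(self, sixteen_row_2sls):
        """Projecting receipt on (1, X, Z, ZX) reproduces the arm-specific
        stage-1 fits with hard zeros in the other arm."""
        d = sixteen_row_2sls
        ones = np.ones(d.n)
        V = np.column_stack([ones, d.X, d.Z, d.Z * d.X]).astype(float)
        F, *_ = np.linalg.lstsq(V, np.column_stack([d.R0, d.R1]).astype(float),
                                rcond=None)
        proj = V @ F
        assert np.allclose(proj[d.Z == 1, 0], 0.0, atol=1e-10)  # C0_hat
        assert np.allclose(proj[d.Z == 0, 1], 0.0, atol=1e-10)  # C1_hat


def arm_mean_dataset(n_per_arm, p0, p1, ybar0, ybar1, spread=0.1):
    """Dataset with exact arm compliance rates and exact *arm-level* outcome
    means (non-compliers have outcome 0, compliers centred at ybar/p)."""
    n0c = int(round(n_per_arm * p0))
    n1c = int(round(n_per_arm * p1))
    ybar0 = ybar0 * n_per_arm / n0c
    ybar1 = ybar1 * n_per_arm / n1c
    Z = np.repeat([0, 1], n_per_arm)
    C = np.concatenate([
        np.r_[np.ones(n0c), np.zeros(n_per_arm - n0c)],
        np.r_[np.ones(n1c), np.zeros(n_per_arm - n1c)],
    ]).astype(int)
    X = np.tile([0, 1], n_per_arm)

    def pm(n, centre):
        y = np.full(n, centre)
        half = n // 2
        y[:half] += spread
        y[n - half:] -= spread
        return y

    Y = np.concatenate([
        pm(n0c, ybar0), np.zeros(n_per_arm - n0c),
        pm(n1c, ybar1), np.zeros(n_per_arm - n1c),
    ])
    return make_dataset(Z=Z, C=C, X=X, Y=Y)


class TestIVBayes:
    def test_degenerate_prior_matches_closed_form(self):
        """With the prior on the standard-receipt effect collapsed to a point
        b0, the posterior contrast centres on
        (ybar1 - ybar0 + b0*p0) / p1 - b0."""
        d = arm_mean_dataset(40, p0=0.9, p1=0.9, ybar0=0.0, ybar1=-0.27)
        for b0 in (0.0, 0.5):
            res = fit_iv_bayes(
                d, PriorSpec(b0, 1e-6), adjust_x=False, variant="plugin",
                chains=2, draws=1500, warmup=300, seed=0,
            )
            closed = (-0.27 - 0.0 + b0 * 0.9) / 0.9 - b0
            assert res.estimate == pytest.approx(closed, abs=0.02)
        assert closed == pytest.approx(-0.3, abs=1e-12)

    def test_full_compliance_contrast_identified_despite_prior(
        self, full_compliance_trial
    ):
        """Under full compliance the receipt contrast is identified, so even a
        badly displaced prior cannot move it from the arm-mean difference."""
        d = full_compliance_trial
        raw = d.Y[d.Z == 1].mean() - d.Y[d.Z == 0].mean()
        res = fit_iv_bayes(d, PriorSpec(5.0, 1.0), adjust_x=False,
                           variant="plugin", chains=2, draws=1500, warmup=300,
                           seed=1)
        assert res.estimate == pytest.approx(raw, abs=0.02)

    def test_reproducible_given_seed(self):
        d = generate_trial(preset("A1"), 3)
        kw = dict(variant="joint", chains=2, draws=400, warmup=200)
        a = fit_iv_bayes(d, PriorSpec(0.5, 1.0), seed=42, **kw)
        b = fit_iv_bayes(d, PriorSpec(0.5, 1.0), seed=42, **kw)
        assert a.estimate == b.estimate
        assert a.interval_lower == b.interval_lower

    def test_convergence_diagnostics_reported(self):
        d = generate_trial(preset("A1"), 4)
        res = fit_iv_bayes(d, PriorSpec(0.5, 1.0), variant="plugin", chains=2,
                           draws=500, warmup=200, seed=0)
        diag = res.diagnostics
        assert np.isfinite(diag["rhat"]) and diag["rhat"] < 1.05
        assert diag["ess"] > 100
        assert isinstance(diag["converged"], bool)
        assert res.interval_lower < res.estimate < res.interval_upper

    def test_plugin_and_joint_variants_agree(self):
        """On a well-behaved trial the plug-in and joint samplers give the
        same posterior centre to within sampling noise."""
        d = generate_trial(preset("A1"), 11)
        prior = make_prior(0.5, "well", "precise")
        a = fit_iv_bayes(d, prior, variant="plugin", chains=2, draws=1500,
                         warmup=300, seed=7)
        b = fit_iv_bayes(d, prior, variant="joint", chains=2, draws=1500,
                         warmup=300, seed=7)
        assert a.estimate == pytest.approx(b.estimate, abs=0.05)

    def test_prior_grid_labels(self):
        p = make_prior(0.5, "mis", "vague")
        assert p.mean == 1.0 and p.sd == 10.0
        assert p.label == "miscentred_vague"
        with pytest.raises(ValueError):
            PriorSpec(0.0, 0.0)
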