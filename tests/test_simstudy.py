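"""Simulation-study engine: determinism, failure capture, filters, summaries."""

import dataclasses

import numpy as np
import pytest

from nicomply.datagen import generate_trial, preset
from nicomply.estimators import EstimateResult
from nicomply.ni import NIDecision
from nicomply.simstudy import (
    EstimatorSpec,
    ReplicationRecord,
    filter_replications,
    precision_increase_pct,
    run_study,
    summarize,
)


def hand_records(estimates, ses=None, declared=None, label="est", itt_estimates=None):
    """Build minimal records by hand for exact-arithmetic checks."""
    n = len(estimates)
    ses = ses or [0.1] * n
    declared = declared or [False] * n
    records = []
    for i in range(n):
        rec = ReplicationRecord(scenario="hand", rep=i, seed=(0, i))
        entries = {label: (estimates[i], ses[i], declared[i])}
        if itt_estimates is not None:
            entries["itt"] = (itt_estimates[i], 0.1, False)
        for lab, (est, se, dec) in entries.items():
            rec.results[lab] = EstimateResult(
                method=lab.split("[")[0], estimate=est, se=se,
                interval_lower=est - 1.96 * se, interval_upper=est + 1.96 * se,
                n_used=100,
            )
            rec.decisions[lab] = NIDecision(
                margin=-0.3, alpha_one_sided=0.025, declared=dec,
                interval_lower=est - 1.96 * se,
            )
        records.append(rec)
    return records


class TestRunStudy:
    def test_identical_seeds_give_identical_records(self):
        cfg = preset("A1")
        a = run_study(cfg, ["itt", "pp"], n_reps=3, master_seed=9)
        b = run_study(cfg, ["itt", "pp"], n_reps=3, master_seed=9)
        for ra, rb in zip(a, b):
            for lab in ra.results:
                assert ra.results[lab].estimate == rb.results[lab].estimate
                assert ra.results[lab].se == rb.results[lab].se
                assert ra.decisions[lab].declared == rb.decisions[lab].declared

    def test_replication_streams_independent_of_grid(self):
        cfg = preset("A1")
        a = run_study(cfg, ["itt"], n_reps=2, master_seed=9)
        b = run_study(cfg, ["itt", "ipw"], n_reps=5, master_seed=9)
        assert a[1].results["itt"].estimate == b[1].results["itt"].estimate

    def test_failures_recorded_without_aborting(self):
        cfg = preset("A1").replace(gamma0=np.inf)  # full compliance
        records = run_study(cfg, ["itt", "iv_interaction"], n_reps=3,
                            master_seed=0)
        for rec in records:
            assert "itt" in rec.results
            assert "iv_interaction" in rec.failures
            assert "proportional" in rec.failures["iv_interaction"]

    def test_empirical_se_close_to_analytic_ols_se(self):
        """ITT empirical SE over replications tracks the classical OLS SE."""
        cfg = preset("A1")
        records = run_study(cfg, ["itt"], n_reps=500, master_seed=13)
        s = summarize(records, truth=-0.3)
        row = s.rows["itt"]
        assert row.empirical_se == pytest.approx(row.mean_model_se, rel=0.2)

    def test_unknown_estimator_rejected(self):
        with pytest.raises(ValueError, match="unknown estimator"):
            run_study(preset("A1"), ["ols"], n_reps=1)


class TestFilters:
    def test_iv_se_outliers_marked_exactly(self):
        ses = [0.1] * 8 + [5.0, 7.0]
        records = hand_records([0.0] * 10, ses=ses, label="iv_interaction",
                               itt_estimates=list(np.linspace(-0.4, -0.2, 10)))
        filtered = filter_replications(records)
        marked = [i for i, r in enumerate(filtered) if "iv_interaction" in r.filtered]
        assert marked == [8, 9]
        # originals untouched (marks, not deletions, on copies)
        assert all(not r.filtered for r in records)

    def test_iv_filter_requires_itt(self):
        records = hand_records([0.0] * 4, label="iv_interaction")
        with pytest.raises(ValueError, match="ITT"):
            filter_replications(records)

    def test_no_outliers_keeps_all_replications(self):
        records = hand_records([0.0] * 6, label="iv_interaction",
                               itt_estimates=list(np.linspace(-1, 1, 6)))
        filtered = filter_replications(records)
        s = summarize(filtered, truth=0.0)
        assert s.rows["iv_interaction"].n_reps_used == 6

    def test_ipw_perfect_prediction_marks_replication(self):
        records = hand_records([0.0] * 3, label="ipw")
        records[1].flags["ipw"] = {"ipw_dropped_obs": True}
        filtered = filter_replications(records)
        assert "ipw" in filtered[1].filtered
        s = summarize(filtered, truth=0.0)
        assert s.rows["ipw"].n_reps_used == 2
        assert s.rows["ipw"].n_filtered == 1

    def test_high_compliance_scenarios_flag_more_ipw_replications(self):
        """Perfect prediction in the weight model becomes common when cell
        compliance probabilities approach 1."""
        from nicomply.datagen import calibrate_intercept

        def flag_fraction(cfg, reps=150):
            records = filter_replications(
                run_study(cfg, ["itt", "ipw"], n_reps=reps, master_seed=3)
            )
            return np.mean(["ipw" in r.filtered for r in records])

        moderate = preset("A2b")
        high = calibrate_intercept(moderate, 0.92)
        assert flag_fraction(high) > flag_fraction(moderate)
        assert flag_fraction(high) > 0


class TestSummaries:
    def test_hand_listed_estimates_bias_is_exact_arithmetic(self):
        estimates = [-0.35, -0.25, -0.31, -0.29, -0.40, -0.20, -0.33, -0.27,
                     -0.36, -0.24]
        records = hand_records(estimates)
        s = summarize(records, truth=-0.3)
        row = s.rows["est"]
        assert row.bias == pytest.approx(np.mean(estimates) + 0.3, abs=1e-15)
        assert row.empirical_se == pytest.approx(np.std(estimates, ddof=1), abs=1e-15)
        assert row.mc_se_bias == pytest.approx(row.empirical_se / np.sqrt(10), abs=1e-15)

    def test_ni_rate_and_binomial_mc_se(self):
        declared = [True] * 3 + [False] * 7
        records = hand_records([0.0] * 10, declared=declared)
        row = summarize(records, truth=0.0).rows["est"]
        assert row.ni_rate_pct == pytest.approx(30.0)
        assert row.mc_se_ni_rate_pct == pytest.approx(
            100 * np.sqrt(0.3 * 0.7 / 10), abs=1e-12
        )

    def test_precision_increase_formula_identities(self):
        assert precision_increase_pct(1.0, 1.0) == 0.0
        assert precision_increase_pct(2.0, 1.0) == pytest.approx(300.0)

    def test_estimator_identical_to_itt_has_zero_precision_increase(self):
        ests = list(np.linspace(-0.5, -0.1, 8))
        records = hand_records(ests, label="pp", itt_estimates=ests)
        s = summarize(records, truth=-0.3)
        assert s.rows["pp"].precision_increase_vs_itt_pct == pytest.approx(0.0, abs=1e-9)

    def test_all_failed_estimator_yields_flagged_empty_row(self):
        records = hand_records([-0.3] * 5, itt_estimates=[-0.3] * 5)
        for rec in records:
            rec.failures["iv_interaction"] = "singular"
        s = summarize(records, truth=-0.3)
        assert s.rows["iv_interaction"].empty
        assert s.rows["iv_interaction"].n_reps_used == 0
        assert not s.rows["est"].empty

    def test_summary_figure_renders(self):
        from nicomply.plots import plot_operating_characteristics

        records = hand_records(list(np.linspace(-0.4, -0.2, 6)),
                               itt_estimates=list(np.linspace(-0.35, -0.25, 6)))
        fig = plot_operating_characteristics([summarize(records, truth=-0.3)])
        assert len(fig.axes) == 3

    def test_per_protocol_bias_under_large_heterogeneity(self):
        """Large treatment-effect heterogeneity across X combined with a large
        between-arm compliance difference biases per-protocol: the complier
        X-distribution no longer matches the population weights."""
        cfg = preset("TEH_X_large_large")
        records = run_study(cfg, ["pp"], n_reps=800, master_seed=17)
        row = summarize(records, truth=-0.3).rows["pp"]
        assert abs(row.bias) > 3 * row.mc_se_bias
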