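"""Figure export for simulation summaries.

One figure, three panels per scenario grid: mean estimates against the true
value, non-inferiority declaration rates against the nominal level, and the
percentage precision increase of ITT over each alternative.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .simstudy import SimulationSummary

__all__ = ["plot_operating_characteristics"]


def plot_operating_characteristics(
    summaries: Sequence[SimulationSummary], nominal_rate_pct: float = 2.5
):
    """Return a matplotlib Figure summarizing a set of scenario summaries."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=False)
    ax_est, ax_t1, ax_prec = axes

    for summary in summaries:
        labels = list(summary.rows)
        est = [summary.rows[l].mean_estimate for l in labels]
        err = [1.96 * summary.rows[l].mc_se_bias for l in labels]
        rates = [summary.rows[l].ni_rate_pct for l in labels]
        prec = [summary.rows[l].precision_increase_vs_itt_pct for l in labels]
        ax_est.errorbar(est, labels, xerr=err, fmt="o", label=summary.scenario)
        ax_t1.plot(rates, labels, "o", label=summary.scenario)
        ax_prec.plot(prec, labels, "o", label=summary.scenario)

    ref = summaries[0]
    ax_est.axvline(ref.truth, color="grey", ls="--", lw=1, label="true value")
    ax_est.set_xlabel("mean estimate")
    ax_t1.axvline(nominal_rate_pct, color="grey", ls="--", lw=1, label="nominal")
    ax_t1.set_xlabel("NI declaration rate (%)")
    ax_prec.axvline(0.0, color="grey", ls="--", lw=1)
    ax_prec.set_xlabel("precision increase of ITT (%)")
    for ax in axes:
        ax.legend(fontsize=7)
    fig.tight_layout()
    return fig
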