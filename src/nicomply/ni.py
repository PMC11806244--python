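"""Non-inferiority decisions from estimate results.

Convention: higher outcome is better, the estimate is new minus standard, and
the margin is the largest acceptable deficit (a negative number, e.g. -0.3).
Non-inferiority is declared when the lower limit of the two-sided
``1 - 2*alpha`` interval lies strictly above the margin; a lower bound exactly
equal to the margin is *not* declared (ties are measure-zero but the rule is
fixed for reproducibility).  For the Bayesian IV the stored credible-interval
bound is used; for the frequentist estimators the normal-based bound is
recomputed at the requested level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy.stats import norm

from .estimators import EstimateResult

__all__ = ["NIDecision", "declare_noninferiority"]


@dataclass
class NIDecision:
    margin: float
    alpha_one_sided: float
    declared: Optional[bool]
    interval_lower: float
    indeterminate: bool = False
    method: str = ""


def declare_noninferiority(
    result: EstimateResult,
    margin: float,
    alpha_one_sided: float = 0.025,
    higher_is_better: bool = True,
) -> NIDecision:
    """Compare the relevant interval bound against the margin.

    ``higher_is_better=False`` recodes the rule for outcomes where lower is
    better (positive margin): non-inferiority then requires the *upper* bound
    to lie strictly below the margin.  A failed fit (non-finite estimate or
    standard error and no usable stored interval) yields an indeterminate
    decision rather than a silent "not declared".
    """
    if not 0.0 < alpha_one_sided < 0.5:
        raise ValueError("alpha_one_sided must lie in (0, 0.5)")
    level = 1.0 - 2.0 * alpha_one_sided

    if result.method == "iv_bayes":
        # posterior quantiles are stored at the fit's level; they cannot be
        # recomputed from (estimate, se) without normality, so require a match
        if abs(result.level - level) > 1e-9:
            raise ValueError(
                f"stored credible interval is at level {result.level}, "
                f"decision requested at {level}; refit with the desired level"
            )
        lower, upper = result.interval_lower, result.interval_upper
        usable = math.isfinite(lower) and math.isfinite(upper)
    else:
        usable = math.isfinite(result.estimate) and math.isfinite(result.se) and result.se >= 0
        if usable:
            half = float(norm.ppf(1.0 - alpha_one_sided)) * result.se
            lower, upper = result.estimate - half, result.estimate + half
        else:
            lower = upper = float("nan")

    if not usable:
        return NIDecision(
            margin=margin,
            alpha_one_sided=alpha_one_sided,
            declared=None,
            interval_lower=float("nan"),
            indeterminate=True,
            method=result.method,
        )

    bound = lower if higher_is_better else upper
    declared = bound > margin if higher_is_better else bound < margin
    return NIDecision(
        margin=margin,
        alpha_one_sided=alpha_one_sided,
        declared=bool(declared),
        interval_lower=float(bound),
        method=result.method,
    )
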