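"""Frequentist estimators of the hypothetical treatment effect.

All estimators return the difference in mean outcome, new minus standard
treatment, under the method's target, together with a standard error and a
two-sided normal-based interval.  Higher outcome is better throughout; the
hypothetical estimand is the contrast under full compliance in both arms.

* :func:`fit_itt` — intention-to-treat OLS of Y on allocation and X over all
  participants.  Targets the treatment-policy effect; coincides with the
  hypothetical estimand only under full compliance (or when non-compliance
  leaves potential outcomes unchanged).
* :func:`fit_pp` — per-protocol: the same regression restricted to compliers.
  Unbiased under conditional exchangeability given X, a correctly specified
  X-outcome association, and no treatment-effect heterogeneity across X.
* :func:`fit_ipw` — inverse-probability-of-compliance weighting: per-arm
  logistic weights from X, then weighted least squares of Y on allocation
  among compliers with a sandwich (robust) variance.
* :func:`fit_iv_interaction` — two-stage least squares with receipt-of-
  standard and receipt-of-new as endogenous regressors and (Z, Z*X) as
  instruments; identified only when predicted compliances are not
  proportional across X levels.

The Bayesian instrumental-variable estimator lives in :mod:`nicomply.bayes`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm

from .datagen import TrialDataset

__all__ = [
    "EstimateResult",
    "FitError",
    "IdentifiabilityError",
    "fit_itt",
    "fit_ipw",
    "fit_iv_interaction",
    "fit_pp",
]

PERFECT_PREDICTION_TOL = 1e-6


class FitError(RuntimeError):
    """An estimator could not be fit on this dataset."""


class IdentifiabilityError(FitError):
    """The model is not identified on this dataset (rank-deficient design)."""


@dataclass
class EstimateResult:
    """One estimator's output on one dataset.

    ``se`` is the classical/sandwich standard error for the frequentist
    estimators and the posterior SD for the Bayesian IV; the interval is a
    two-sided normal-based interval (equal-tailed credible interval for the
    Bayesian IV) at ``level``.
    """

    method: str
    estimate: float
    se: float
    interval_lower: float
    interval_upper: float
    level: float = 0.95
    n_used: int = 0
    diagnostics: dict = field(default_factory=dict)


def _z(level: float) -> float:
    return float(norm.ppf(0.5 + level / 2.0))


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    """Raise naming the first column that is linearly dependent on its
    predecessors (constant X, X identical to Z, ...)."""
    tol = np.finfo(float).eps * max(design.shape) * 100
    rank_prev = 0
    for j in range(design.shape[1]):
        sub = design[:, : j + 1]
        s = np.linalg.svd(sub, compute_uv=False)
        rank = int(np.sum(s > tol * s[0]))
        if rank == rank_prev:
            raise FitError(
                f"design is rank deficient: column {names[j]!r} is collinear "
                "with the preceding columns"
            )
        rank_prev = rank


def _adjusted_ols(
    data: TrialDataset,
    mask: np.ndarray,
    method: str,
    level: float,
    diagnostics: dict,
) -> EstimateResult:
    Z = data.Z[mask].astype(float)
    X = data.X[mask].astype(float)
    Y = data.Y[mask]
    if not (np.any(Z == 0) and np.any(Z == 1)):
        raise FitError("both arms must be non-empty in the analysis population")
    design = np.column_stack([np.ones_like(Z), Z, X])
    _check_full_rank(design, ["intercept", "Z", "X"])
    res = sm.OLS(Y, design).fit()
    est = float(res.params[1])
    se = float(res.bse[1])
    half = _z(level) * se
    diagnostics = dict(diagnostics)
    diagnostics.update(
        residual_sd=float(np.sqrt(res.scale)), df_resid=int(res.df_resid)
    )
    return EstimateResult(
        method=method,
        estimate=est,
        se=se,
        interval_lower=est - half,
        interval_upper=est + half,
        level=level,
        n_used=int(mask.sum()),
        diagnostics=diagnostics,
    )


def fit_itt(data: TrialDataset, level: float = 0.95) -> EstimateResult:
    """Intention-to-treat: OLS of Y on intercept, Z and X, all participants."""
    data.require_both_arms()
    mask = np.ones(data.n, dtype=bool)
    return _adjusted_ols(data, mask, "itt", level, {})


def fit_pp(data: TrialDataset, level: float = 0.95) -> EstimateResult:
    """Per-protocol: the ITT regression restricted to compliers (C=1)."""
    data.require_both_arms()
    mask = data.C == 1
    excluded = {
        f"excluded_arm{z}": int(np.sum((data.Z == z) & (data.C == 0)))
        for z in (0, 1)
    }
    for z in (0, 1):
        if not np.any(mask & (data.Z == z)):
            raise FitError(f"no compliers in arm {z}")
    return _adjusted_ols(data, mask, "pp", level, excluded)


def _saturated_compliance_probs(
    Z: np.ndarray, X: np.ndarray, C: np.ndarray, arm: int
) -> dict[int, float]:
    """Per-X-cell compliance proportions within one arm.

    With a single binary covariate the per-arm logistic regression of C on
    intercept + X is saturated, so its MLE fitted probabilities are exactly
    the cell proportions (including the separated limits 0 and 1).
    """
    out = {}
    in_arm = Z == arm
    for x in (0, 1):
        cell = in_arm & (X == x)
        if cell.any():
            out[x] = float(C[cell].mean())
    return out


def fit_ipw(
    data: TrialDataset,
    level: float = 0.95,
    perfect_prediction_tol: float = PERFECT_PREDICTION_TOL,
) -> EstimateResult:
    """Inverse probability weighting with a sandwich variance.

    Stage 1 fits a logistic model of compliance on X within each arm
    separately; stage 2 is weighted least squares of Y on intercept and Z
    among compliers, weighting each complier by the inverse of their fitted
    compliance probability, with an HC1 sandwich standard error.

    A fully compliant arm needs no reweighting (all weights 1).  When
    compliance varies within an arm but a covariate cell predicts it
    perfectly (fitted probability outside
    ``[tol, 1-tol]``), the fit is flagged: compliers in such a cell keep the
    limit weight 1, and the count of observations that perfect-prediction
    software conventions would drop is recorded so that replication-level
    filtering can exclude the whole replication.
    """
    data.require_both_arms()
    Z, X, C, Y = data.Z, data.X, data.C, data.Y

    probs: dict[tuple[int, int], float] = {}
    n_flagged = 0
    flagged_by_arm = {0: 0, 1: 0}
    for arm in (0, 1):
        in_arm = Z == arm
        c_arm = C[in_arm]
        if not c_arm.any():
            raise FitError(f"no compliers in arm {arm}")
        if c_arm.all():
            # degenerate but well-defined: no reweighting needed
            for x in (0, 1):
                probs[(arm, x)] = 1.0
            continue
        cell_p = _saturated_compliance_probs(Z, X, C, arm)
        for x, p in cell_p.items():
            probs[(arm, x)] = p
            if p < perfect_prediction_tol or p > 1 - perfect_prediction_tol:
                n_cell = int(np.sum(in_arm & (X == x)))
                n_flagged += n_cell
                flagged_by_arm[arm] += n_cell

    compliers = C == 1
    w = np.full(data.n, np.nan)
    for (arm, x), p in probs.items():
        cell = (Z == arm) & (X == x) & compliers
        # a cell containing compliers has p >= 1/n_cell, so this division is
        # safe; all-complier cells get the limit weight 1
        w[cell] = 1.0 / p

    zc = Z[compliers].astype(float)
    if not (np.any(zc == 0) and np.any(zc == 1)):
        raise FitError("no compliers in one arm after weighting")
    design = np.column_stack([np.ones_like(zc), zc])
    res = sm.WLS(Y[compliers], design, weights=w[compliers]).fit(cov_type="HC1")
    est = float(res.params[1])
    se = float(res.bse[1])
    half = _z(level) * se
    wc = w[compliers]
    diagnostics = dict(
        cell_probabilities={k: probs[k] for k in sorted(probs)},
        weight_min=float(wc.min()),
        weight_max=float(wc.max()),
        n_flagged_perfect_prediction=n_flagged,
        flagged_by_arm=flagged_by_arm,
        perfect_prediction=n_flagged > 0,
    )
    return EstimateResult(
        method="ipw",
        estimate=est,
        se=se,
        interval_lower=est - half,
        interval_upper=est + half,
        level=level,
        n_used=int(compliers.sum()),
        diagnostics=diagnostics,
    )


def fit_iv_interaction(
    data: TrialDataset, level: float = 0.95, rcond: float = 1e-8
) -> EstimateResult:
    """Two-stage least squares with an allocation-by-covariate instrument.

    Endogenous regressors are the receipt indicators R0 and R1; instruments
    are Z and Z*X, with intercept and X exogenous.  Because C1 is identically
    zero in arm 0 (and C0 in arm 1), projecting the receipt indicators on the
    instrument set reproduces the arm-specific stage-1 regressions of receipt
    on X, with hard zeros in the opposite arm.  The treatment effect is the
    contrast of the two receipt coefficients in the second stage, with the
    conventional 2SLS covariance (residual variance from the *original*
    regressors) and the delta rule for the contrast.

    Raises :class:`IdentifiabilityError` when the projected design is
    (near-)singular — i.e., when the predicted compliances are proportional
    across X levels, as under full compliance in both arms.
    """
    data.require_both_arms()
    Z = data.Z.astype(float)
    X = data.X.astype(float)
    Y = data.Y
    R0 = data.R0.astype(float)
    R1 = data.R1.astype(float)
    n = data.n

    ones = np.ones(n)
    regressors = np.column_stack([ones, X, R0, R1])
    instruments = np.column_stack([ones, X, Z, Z * X])

    s_inst = np.linalg.svd(instruments, compute_uv=False)
    if s_inst[-1] < rcond * s_inst[0]:
        raise IdentifiabilityError(
            "instrument matrix (intercept, X, Z, Z*X) is rank deficient; "
            "X must vary to form the interaction instrument"
        )

    first_stage, *_ = np.linalg.lstsq(instruments, regressors, rcond=None)
    projected = instruments @ first_stage
    s_proj = np.linalg.svd(projected, compute_uv=False)
    if s_proj[-1] < rcond * s_proj[0]:
        raise IdentifiabilityError(
            "projected design is singular: the predicted compliances are "
            "proportional across levels of X (e.g. full compliance in both "
            "arms), so the receipt-of-standard and receipt-of-new effects "
            "cannot be separated"
        )

    beta, *_ = np.linalg.lstsq(projected, Y, rcond=None)
    resid = Y - regressors @ beta
    sigma2 = float(resid @ resid) / n  # conventional 2SLS (no df correction)
    cov = sigma2 * np.linalg.inv(projected.T @ projected)
    contrast = np.array([0.0, 0.0, -1.0, 1.0])
    est = float(contrast @ beta)
    se = float(np.sqrt(contrast @ cov @ contrast))
    half = _z(level) * se

    # stage-1 interaction strength: spread of predicted receipt across X
    # within the relevant arm
    cell_receipt = {}
    for arm, R in ((0, R0), (1, R1)):
        for x in (0, 1):
            cell = (data.Z == arm) & (data.X == x)
            if cell.any():
                cell_receipt[(arm, x)] = float(R[cell].mean())
    strength = {
        arm: cell_receipt.get((arm, 1), np.nan) - cell_receipt.get((arm, 0), np.nan)
        for arm in (0, 1)
    }
    diagnostics = dict(
        smallest_singular_value=float(s_proj[-1]),
        singular_value_ratio=float(s_proj[-1] / s_proj[0]),
        stage1_interaction_strength=strength,
        cell_receipt_rates={k: cell_receipt[k] for k in sorted(cell_receipt)},
        coefficients=dict(
            zip(["intercept", "X", "R0", "R1"], (float(b) for b in beta))
        ),
    )
    return EstimateResult(
        method="iv_interaction",
        estimate=est,
        se=se,
        interval_lower=est - half,
        interval_upper=est + half,
        level=level,
        n_used=n,
        diagnostics=diagnostics,
    )
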