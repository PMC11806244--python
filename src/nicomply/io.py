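"""Trial-table and study-configuration serialization.

Trial data travel as delimited text with header columns ``id, Z, X, C, Y``
and an optional latent ``U`` (written for simulated data, treated as
non-observable on read).  Study configurations are a single YAML document;
unknown keys are rejected before any computation.  Replication records and
summaries serialize to tidy long-format CSV (one metric per row) so results
diff cleanly and figures can be regenerated from them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .bayes import PriorSpec
from .datagen import ScenarioConfig, TrialDataset, preset
from .estimators import EstimateResult
from .ni import NIDecision
from .simstudy import EstimatorSpec, ReplicationRecord, SimulationSummary

__all__ = [
    "ConfigError",
    "SchemaError",
    "StudyConfig",
    "load_study_config",
    "read_trial_table",
    "records_to_frame",
    "frame_to_records",
    "summary_to_tidy_frame",
    "write_trial_table",
]

_FLOAT_FMT = "%.10g"


class SchemaError(ValueError):
    """A trial table violated the expected schema."""


class ConfigError(ValueError):
    """A study configuration file is invalid."""


REQUIRED_COLUMNS = ("id", "Z", "X", "C", "Y")


def read_trial_table(path) -> TrialDataset:
    """Read and validate a delimited trial table.

    Errors name the offending column and (1-based data) row.  A ``U`` column,
    if present, is loaded but flagged non-observable.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    for col in ("Z", "X", "C") + (("U",) if "U" in df.columns else ()):
        vals = df[col]
        bad = ~vals.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise SchemaError(
                f"column {col!r} must be binary 0/1; offending value "
                f"{vals.iloc[row - 1]!r} in row {row}"
            )
    y = pd.to_numeric(df["Y"], errors="coerce")
    bad = ~np.isfinite(y)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise SchemaError(
            f"column 'Y' must be finite numeric; offending value "
            f"{df['Y'].iloc[row - 1]!r} in row {row}"
        )
    return TrialDataset(
        id=df["id"].to_numpy(),
        Z=df["Z"].to_numpy(),
        C=df["C"].to_numpy(),
        X=df["X"].to_numpy(),
        Y=y.to_numpy(),
        U=df["U"].to_numpy() if "U" in df.columns else None,
    )


def write_trial_table(data: TrialDataset, path) -> None:
    data.to_frame(include_unobserved=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


# --------------------------------------------------------------------------
# Study configuration


@dataclass
class StudyConfig:
    """Validated study configuration: scenarios x estimators grid settings."""

    scenarios: list
    estimators: list[EstimatorSpec]
    n_reps: int = 2000
    master_seed: int = 0
    margin: float = -0.3
    alpha_one_sided: float = 0.025
    output: Optional[str] = None


_TOP_KEYS = {
    "scenarios",
    "estimators",
    "n_reps",
    "master_seed",
    "margin",
    "alpha_one_sided",
    "output",
}
_ESTIMATOR_KEYS = {"name", "label", "prior", "variant", "chains", "draws", "warmup", "level"}
_PRIOR_KEYS = {"mean", "sd", "label"}


def _parse_scenario(entry) -> ScenarioConfig:
    if isinstance(entry, str):
        return preset(entry)
    if isinstance(entry, dict):
        try:
            return ScenarioConfig(**entry)
        except TypeError as exc:
            raise ConfigError(f"invalid scenario block: {exc}") from None
    raise ConfigError(f"scenario entries must be labels or mappings, got {entry!r}")


def _parse_estimator(entry) -> EstimatorSpec:
    if isinstance(entry, str):
        return EstimatorSpec(entry)
    if not isinstance(entry, dict):
        raise ConfigError(f"estimator entries must be names or mappings, got {entry!r}")
    unknown = set(entry) - _ESTIMATOR_KEYS
    if unknown:
        raise ConfigError(f"unknown estimator keys: {sorted(unknown)}")
    entry = dict(entry)
    name = entry.pop("name", None)
    if name is None:
        raise ConfigError("estimator mapping needs a 'name' key")
    label = entry.pop("label", "")
    prior = entry.pop("prior", None)
    options = dict(entry)
    if prior is not None:
        unknown = set(prior) - _PRIOR_KEYS
        if unknown:
            raise ConfigError(f"unknown prior keys: {sorted(unknown)}")
        options["prior"] = PriorSpec(**prior)
    try:
        return EstimatorSpec(name, options, label=label)
    except ValueError as exc:
        raise ConfigError(str(exc)) from None


def load_study_config(path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("study config must be a YAML mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "scenarios" not in raw or "estimators" not in raw:
        raise ConfigError("config must declare 'scenarios' and 'estimators'")
    scenarios = [_parse_scenario(s) for s in raw["scenarios"]]
    estimators = [_parse_estimator(e) for e in raw["estimators"]]
    cfg = StudyConfig(
        scenarios=scenarios,
        estimators=estimators,
        n_reps=int(raw.get("n_reps", 2000)),
        master_seed=int(raw.get("master_seed", 0)),
        margin=float(raw.get("margin", -0.3)),
        alpha_one_sided=float(raw.get("alpha_one_sided", 0.025)),
        output=raw.get("output"),
    )
    if cfg.n_reps < 1:
        raise ConfigError("n_reps must be at least 1")
    if not 0.0 < cfg.alpha_one_sided < 0.5:
        raise ConfigError("alpha_one_sided must lie in (0, 0.5)")
    return cfg


# --------------------------------------------------------------------------
# Records and summaries


def records_to_frame(records: Sequence[ReplicationRecord]) -> pd.DataFrame:
    """Flatten replication records to one row per (replication, estimator)."""
    rows = []
    for rec in records:
        labels = set(rec.results) | set(rec.failures)
        for lab in sorted(labels):
            res = rec.results.get(lab)
            dec = rec.decisions.get(lab)
            flags = rec.flags.get(lab, {})
            rows.append(
                dict(
                    scenario=rec.scenario,
                    rep=rec.rep,
                    master_seed=rec.seed[0],
                    estimator=lab,
                    estimate=res.estimate if res else np.nan,
                    se=res.se if res else np.nan,
                    interval_lower=res.interval_lower if res else np.nan,
                    interval_upper=res.interval_upper if res else np.nan,
                    declared=(
                        int(dec.declared)
                        if dec is not None and dec.declared is not None
                        else np.nan
                    ),
                    failed=int(res is None),
                    failure_reason=rec.failures.get(lab, ""),
                    ipw_dropped_obs=int(bool(flags.get("ipw_dropped_obs", False))),
                    bayes_nonconverged=int(bool(flags.get("bayes_nonconverged", False))),
                    filtered_out=int(lab in rec.filtered),
                )
            )
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[ReplicationRecord]:
    """Rebuild records (point estimates, decisions, flags) from a stored
    replication table, sufficient for filtering and summarizing."""
    records = []
    for (scenario, rep), grp in df.groupby(["scenario", "rep"], sort=True):
        rec = ReplicationRecord(
            scenario=str(scenario),
            rep=int(rep),
            seed=(int(grp["master_seed"].iloc[0]), int(rep)),
        )
        for _, row in grp.iterrows():
            lab = row["estimator"]
            if row["failed"]:
                rec.failures[lab] = str(row.get("failure_reason", ""))
                continue
            method = lab.split("[")[0]
            rec.results[lab] = EstimateResult(
                method=method,
                estimate=float(row["estimate"]),
                se=float(row["se"]),
                interval_lower=float(row["interval_lower"]),
                interval_upper=float(row["interval_upper"]),
                n_used=0,
                diagnostics={
                    "perfect_prediction": bool(row.get("ipw_dropped_obs", 0))
                },
            )
            declared = row.get("declared")
            rec.decisions[lab] = NIDecision(
                margin=np.nan,
                alpha_one_sided=np.nan,
                declared=None if pd.isna(declared) else bool(declared),
                interval_lower=float(row["interval_lower"]),
                method=method,
            )
            flags = {}
            if bool(row.get("ipw_dropped_obs", 0)):
                flags["ipw_dropped_obs"] = True
            if bool(row.get("bayes_nonconverged", 0)):
                flags["bayes_nonconverged"] = True
            if flags:
                rec.flags[lab] = flags
            if bool(row.get("filtered_out", 0)):
                rec.filtered.add(lab)
        records.append(rec)
    return records


def summary_to_tidy_frame(summary: SimulationSummary) -> pd.DataFrame:
    """Long-format summary: columns scenario, estimator, metric, value, mc_se,
    n_reps_used (documented stable schema)."""
    metric_mcse = {
        "mean_estimate": "mc_se_bias",
        "bias": "mc_se_bias",
        "ni_rate_pct": "mc_se_ni_rate_pct",
    }
    plain = [
        "empirical_se",
        "mean_model_se",
        "rel_model_se_error_pct",
        "precision_increase_vs_itt_pct",
        "n_failed",
        "n_filtered",
    ]
    rows = []
    for lab in sorted(summary.rows):
        r = summary.rows[lab]
        d = dataclasses.asdict(r)
        for metric, mcse_key in metric_mcse.items():
            rows.append(
                dict(
                    scenario=summary.scenario,
                    estimator=lab,
                    metric=metric,
                    value=d[metric],
                    mc_se=d[mcse_key],
                    n_reps_used=r.n_reps_used,
                )
            )
        for metric in plain:
            rows.append(
                dict(
                    scenario=summary.scenario,
                    estimator=lab,
                    metric=metric,
                    value=d[metric],
                    mc_se=np.nan,
                    n_reps_used=r.n_reps_used,
                )
            )
    return pd.DataFrame(rows)


def write_tidy_summary(summaries: Sequence[SimulationSummary], path) -> None:
    frames = [summary_to_tidy_frame(s) for s in summaries]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
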