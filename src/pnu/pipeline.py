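"""End-to-end orchestration of the PNU analysis.

``run_design`` executes one (definition, caliper) configuration on
in-memory tables: cohort assembly, exposure sets, within-set sampling,
TCPS fit, prediction for all members, positivity screening,
chronological matching, balance diagnostics, as-treated follow-up and
the three subgroup Cox contrasts.  ``run_all`` loops configurations
from a :class:`RunConfig` and assembles one machine-readable report
(same keys per configuration, so definitions are directly comparable)
plus a forest-plot-style markdown summary.  Stage seeds are split
deterministically from the master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pnu.cohort import build_treatment_episodes, classify_new_users
from pnu.exposure import ExposureSetDefinition, build_exposure_sets
from pnu.followup import (
    balance_table,
    build_followup,
    fit_cox_robust,
    sample_unmatched_group,
)
from pnu.matching import check_positivity, match_chronological, match_rate
from pnu.tcps import (
    CovariateEncoder,
    SamplingPlan,
    fit_tcps,
    sample_within_sets,
    score_all_members,
)

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = {"age": "continuous", "male": "binary", "comorbidity": "binary"}


@dataclass
class RunConfig:
    """One full analysis request (paths or in-memory tables)."""

    patients: str | pd.DataFrame
    prescriptions: str | pd.DataFrame
    events: str | pd.DataFrame
    window: tuple[str, str] = ("2000-01-01", "2004-12-31")
    washout_days: int = 365
    grace_days: int = 30
    definitions: tuple[str, ...] = ("prescription", "time", "hybrid")
    calipers: tuple[int, ...] = (30,)
    target_per_set: int = 50
    seed: int = 0
    study_end: str | None = None
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    include_calendar_year: bool = True
    cluster_robust_by_pair: bool = False

    def __post_init__(self) -> None:
        if not self.definitions:
            raise ValueError("at least one exposure-set definition is required")
        if any(c <= 0 for c in self.calipers):
            raise ValueError("calipers must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("window", "definitions", "calipers"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    df = pd.read_csv(table)
    for col in df.columns:
        if col.endswith("_date") or col in ("issue_date", "event_date"):
            df[col] = pd.to_datetime(df[col])
    return df


def _encoder_from(covariates: dict, include_year: bool) -> CovariateEncoder:
    return CovariateEncoder(
        continuous=tuple(n for n, k in covariates.items() if k == "continuous"),
        binary=tuple(n for n, k in covariates.items() if k == "binary"),
        categorical=tuple(n for n, k in covariates.items() if k == "categorical"),
        include_calendar_year=include_year,
    )


def run_design(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    events: pd.DataFrame,
    definition: ExposureSetDefinition,
    window=("2000-01-01", "2004-12-31"),
    washout_days: int = 365,
    grace_days: int = 30,
    target_per_set: int = 50,
    seed: int = 0,
    study_end=None,
    covariates: dict | None = None,
    include_calendar_year: bool = True,
    cluster_robust_by_pair: bool = False,
    return_tables: bool = False,
) -> dict:
    """Run one configuration; returns a result dict (and, optionally,
    the intermediate tables under ``"tables"``)."""
    covariates = dict(covariates if covariates is not None else DEFAULT_COVARIATES)
    study_end = pd.Timestamp(study_end) if study_end is not None else pd.Timestamp(window[1])
    sample_seed, unmatched_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(2)
    )

    members, excluded = classify_new_users(patients, prescriptions, window, washout_days)
    episodes = build_treatment_episodes(prescriptions, grace_days=grace_days)
    sets = build_exposure_sets(members, prescriptions, definition)

    stacked = sample_within_sets(sets, SamplingPlan(target_per_set=target_per_set, seed=sample_seed))
    merged = stacked.merge(patients, on="patient_id", how="left")
    encoder = _encoder_from(covariates, include_calendar_year)
    X, names = encoder.fit_transform(merged)
    model = fit_tcps(
        X, merged["set_id"].to_numpy(), merged["is_treated"].to_numpy(), merged["weight"].to_numpy()
    )

    scored = score_all_members(model, encoder, sets, patients)
    positivity = check_positivity(scored)
    pairs, unmatched = match_chronological(scored, positivity, sets.treated)

    unmatched_sample = sample_unmatched_group(sets, unmatched_seed)
    balance = (
        balance_table(unmatched_sample, pairs, patients, covariates)
        if len(pairs) and len(unmatched_sample)
        else pd.DataFrame()
    )

    followup = build_followup(pairs, episodes, events, study_end) if len(pairs) else pd.DataFrame()
    effects = {}
    for sub in ("overall", "prevalent", "incident"):
        if len(followup):
            effects[sub] = fit_cox_robust(
                followup, subgroup=sub, cluster_by_pair=cluster_robust_by_pair
            ).to_dict()
        else:
            effects[sub] = None

    result = {
        "definition": definition.kind,
        "caliper_days": definition.caliper_days if definition.uses_caliper else None,
        "n_members": int(len(members)),
        "n_excluded": int(len(excluded)),
        "n_sets": int(sets.n_sets),
        "n_empty_sets": int(len(sets.empty_sets)),
        "n_dropped_positivity": int((~positivity["kept"]).sum()),
        "n_pairs": int(len(pairs)),
        "match_rate": match_rate(pairs, sets.treated),
        "tcps": {
            "coef": dict(zip(names, map(float, model.coef_))),
            "converged": bool(model.converged_),
            "loglik": float(model.loglik_),
            "n_sets_used": int(model.n_sets_used_),
        },
        "balance": balance.to_dict(orient="records") if len(balance) else [],
        "max_asd_matched": float(balance["absolute_standardized_difference"].max())
        if len(balance)
        else None,
        "effects": effects,
    }
    if return_tables:
        result["tables"] = {
            "members": members,
            "excluded": excluded,
            "episodes": episodes,
            "sets": sets,
            "stacked": stacked,
            "scored": scored,
            "positivity": positivity,
            "pairs": pairs,
            "unmatched": unmatched,
            "followup": followup,
            "balance_df": balance,
        }
    return result


def run_all(config: RunConfig) -> dict:
    """Run every requested (definition, caliper) configuration.

    A failing configuration is recorded with its error and the others
    proceed.  The prescription-based definition ignores the caliper list
    (logged) and runs once.
    """
    patients = _load(config.patients)
    prescriptions = _load(config.prescriptions)
    events = _load(config.events)

    requested: list[ExposureSetDefinition] = []
    for kind in config.definitions:
        if kind == "prescription":
            if len(config.calipers) > 1 or config.calipers != (30,):
                logger.info("prescription-based definition ignores the caliper list")
            requested.append(ExposureSetDefinition("prescription"))
        else:
            for cal in config.calipers:
                requested.append(ExposureSetDefinition(kind, caliper_days=cal))

    configurations = []
    for i, definition in enumerate(requested):
        try:
            res = run_design(
                patients,
                prescriptions,
                events,
                definition,
                window=config.window,
                washout_days=config.washout_days,
                grace_days=config.grace_days,
                target_per_set=config.target_per_set,
                seed=config.seed + i,
                study_end=config.study_end,
                covariates=config.covariates,
                include_calendar_year=config.include_calendar_year,
                cluster_robust_by_pair=config.cluster_robust_by_pair,
            )
        except Exception as exc:  # a stage failure aborts this configuration only
            logger.error("configuration %s failed: %s", definition, exc)
            res = {
                "definition": definition.kind,
                "caliper_days": definition.caliper_days if definition.uses_caliper else None,
                "error": str(exc),
            }
        configurations.append(res)
    return {"seed": config.seed, "configurations": configurations}


def report_markdown(report: dict) -> str:
    """Forest-plot-style summary table of HRs per configuration."""
    lines = [
        "| Definition | Caliper | Subgroup | HR (95% CI) | CLR | Matched |",
        "|---|---|---|---|---|---|",
    ]
    for cfg in report["configurations"]:
        if "error" in cfg:
            lines.append(f"| {cfg['definition']} | {cfg.get('caliper_days') or '-'} | "
                         f"error | {cfg['error']} | | |")
            continue
        for sub in ("overall", "prevalent", "incident"):
            eff = cfg["effects"][sub]
            if eff is None or not np.isfinite(eff.get("hr", np.nan)):
                cell, clr = "n/e", ""
            else:
                cell = f"{eff['hr']:.2f} ({eff['ci95_low']:.2f}-{eff['ci95_high']:.2f})"
                clr = f"{eff['confidence_limit_ratio']:.2f}"
            lines.append(
                f"| {cfg['definition']} | {cfg.get('caliper_days') or '-'} | {sub} "
                f"| {cell} | {clr} | {cfg['match_rate']['overall']:.2f} |"
            )
    return "\n".join(lines) + "\n"


def write_report(report: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    (outdir / "report.md").write_text(report_markdown(report))
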