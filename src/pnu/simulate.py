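"""Synthetic longitudinal EHR generator with known ground truth.

Generates the three analysis-facing tables the PNU pipeline consumes —
``patients`` (registration date + baseline covariates), ``prescriptions``
(drug class, issue date, supply days) and ``events`` (outcome and
censoring events) — together with a quarantined truth record holding the
latent quantities (true treatment log hazard ratio, latent switch and
outcome times) that the pipeline must never read.

The generative model emulates the structural features a prevalent
new-user analysis relies on:

* staggered cohort entry, uniform over a multi-year study window;
* calendar-time uptake of the newer study drug — at initiation the drug
  is study vs comparator with a per-year probability, shifted on the
  logit scale by covariates;
* covariate-driven switching — comparator initiators carry an
  exponential switch clock with log-rate ``intercept + coefs . x``; the
  first scheduled refill at/after the latent switch time is issued as a
  study-drug prescription;
* repeat prescriptions of fixed supply length separated by random refill
  gaps, with a per-refill stop probability (non-persistence);
* an exponential proportional-hazards outcome with linear predictor
  ``true_log_hr * treated(t) + confounder_log_hrs . x`` where treatment
  is time-fixed from the study-drug index date;
* independent exponential censoring processes (death, transfer out of
  practice, cirrhosis-analogue diagnosis).

Continuous covariates enter every linear predictor standardized by the
mean/sd of their sampling distribution, so coefficients are per-SD.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

STUDY = "study"
COMPARATOR = "comparator"

#: covariates that drive both treatment choice/switching and the outcome
#: in configurations built by :func:`generate_confounded_scenario`
CONFOUNDED_DRIVERS = ("age", "comorbidity")


@dataclass(frozen=True)
class CovariateSpec:
    """One baseline covariate: name, kind and sampling parameters.

    ``continuous`` expects ``{"mean": .., "sd": ..}``; ``binary`` expects
    ``{"p": ..}``; ``categorical`` expects ``{"levels": [...], "probs": [...]}``.
    """

    name: str
    kind: str
    params: Mapping[str, object]

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")


def default_covariates() -> list[CovariateSpec]:
    """Age (years), sex and a chronic-comorbidity flag, on scales typical
    of an older osteoarthritis-like primary-care population."""
    return [
        CovariateSpec("age", "continuous", {"mean": 67.0, "sd": 12.0}),
        CovariateSpec("male", "binary", {"p": 0.35}),
        CovariateSpec("comorbidity", "binary", {"p": 0.35}),
    ]


def _default_uptake() -> dict[int, float]:
    # rising uptake of a newly introduced drug over the window
    return {2000: 0.10, 2001: 0.18, 2002: 0.28, 2003: 0.38, 2004: 0.45}


@dataclass
class SimulationConfig:
    """Ground-truth configuration for :func:`generate_population`.

    Rates are per person-day.  ``uptake_curve`` maps calendar year to the
    baseline probability that an initiation is the study drug; years
    outside the map are clamped to the nearest specified year.
    """

    n_patients: int = 2000
    study_window: tuple[str, str] = ("2000-01-01", "2004-12-31")
    covariate_spec: Sequence[CovariateSpec] = field(default_factory=default_covariates)
    uptake_curve: Mapping[int, float] = field(default_factory=_default_uptake)
    choice_log_odds: Mapping[str, float] = field(default_factory=dict)
    switch_log_hazard: Mapping[str, float] = field(
        default_factory=lambda: {"intercept": math.log(6e-4)}
    )
    rx_duration_days: int = 28
    refill_gap_mean_days: float = 7.0
    refill_stop_prob: float = 0.06
    true_log_hr: float = 0.0
    outcome_baseline_rate: float = 2.5e-4
    confounder_log_hrs: Mapping[str, float] = field(default_factory=dict)
    censor_rates: Mapping[str, float] = field(
        default_factory=lambda: {"death": 4e-5, "transfer": 8e-5, "cirrhosis": 5e-6}
    )
    short_history_frac: float = 0.02
    registration_lead_mean_days: float = 1500.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        start, end = (pd.Timestamp(d) for d in self.study_window)
        if start >= end:
            raise ValueError("study_window start must precede end")
        if self.rx_duration_days < 1:
            raise ValueError("rx_duration_days must be >= 1")
        for year, p in self.uptake_curve.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"uptake probability for {year} outside [0, 1]")
        if self.outcome_baseline_rate < 0:
            raise ValueError("outcome_baseline_rate must be nonnegative")
        for cause, rate in self.censor_rates.items():
            if rate < 0:
                raise ValueError(f"censor rate for {cause!r} must be nonnegative")
        if not 0.0 <= self.refill_stop_prob <= 1.0:
            raise ValueError("refill_stop_prob outside [0, 1]")


@dataclass
class SyntheticDataset:
    """Analysis-facing tables plus the quarantined truth record.

    ``truth`` holds latent per-patient quantities and the true effect; it
    is written to a separate file and must never feed the pipeline.
    """

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    events: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(outdir / "patients.csv", index=False, date_format="%Y-%m-%d")
        self.prescriptions.to_csv(
            outdir / "prescriptions.csv", index=False, date_format="%Y-%m-%d"
        )
        self.events.to_csv(outdir / "events.csv", index=False, date_format="%Y-%m-%d")
        truth = dict(self.truth)
        truth_patients = truth.pop("patients")
        truth["patients"] = json.loads(
            truth_patients.to_json(orient="records", date_format="iso")
        )
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, default=str))


def _draw_covariates(
    rng: np.random.Generator, spec: Sequence[CovariateSpec], n: int
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Return raw covariate columns and the standardized/indicator map
    used by linear predictors (keys ``name`` or ``name:level``)."""
    raw: dict[str, np.ndarray] = {}
    zmap: dict[str, np.ndarray] = {}
    for cv in spec:
        if cv.kind == "continuous":
            x = rng.normal(cv.params["mean"], cv.params["sd"], n)
            raw[cv.name] = x
            zmap[cv.name] = (x - cv.params["mean"]) / cv.params["sd"]
        elif cv.kind == "binary":
            x = (rng.random(n) < cv.params["p"]).astype(np.int64)
            raw[cv.name] = x
            zmap[cv.name] = x.astype(float)
        else:
            levels = list(cv.params["levels"])
            probs = np.asarray(cv.params["probs"], float)
            idx = rng.choice(len(levels), size=n, p=probs / probs.sum())
            raw[cv.name] = np.asarray(levels, object)[idx]
            for j, lev in enumerate(levels[1:], start=1):
                zmap[f"{cv.name}:{lev}"] = (idx == j).astype(float)
    return raw, zmap


def _lin_pred(zmap: Mapping[str, np.ndarray], coefs: Mapping[str, float], n: int) -> np.ndarray:
    lp = np.zeros(n)
    for name, coef in coefs.items():
        if name == "intercept":
            lp += coef
        else:
            if name not in zmap:
                raise KeyError(f"coefficient refers to unknown covariate {name!r}")
            lp += coef * zmap[name]
    return lp


def _exponential_times(rng: np.random.Generator, rate: np.ndarray | float, n: int) -> np.ndarray:
    """Exponential event times; rate 0 gives +inf (event never happens)."""
    e = rng.exponential(1.0, n)
    rate = np.broadcast_to(np.asarray(rate, float), (n,))
    with np.errstate(divide="ignore"):
        return np.where(rate > 0, e / np.where(rate > 0, rate, 1.0), np.inf)


def generate_population(config: SimulationConfig) -> SyntheticDataset:
    """Generate patients, prescriptions and events under ``config``.

    Bit-reproducible for a fixed seed: the random stream is consumed in a
    fixed order regardless of parameter values.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    start = pd.Timestamp(config.study_window[0])
    end = pd.Timestamp(config.study_window[1])
    horizon = float((end - start).days)
    dur = config.rx_duration_days

    entry_off = rng.integers(0, int(horizon) + 1, n).astype(float)
    raw_cov, zmap = _draw_covariates(rng, config.covariate_spec, n)

    # registered history: mostly long, a small fraction below one year
    lead = np.rint(365.0 + rng.exponential(config.registration_lead_mean_days, n))
    short = rng.random(n) < config.short_history_frac
    short_lead = rng.integers(30, 365, n).astype(float)
    lead = np.where(short, short_lead, lead)

    # initiation drug: per-year uptake shifted by covariates on logit scale
    entry_year = (start + pd.to_timedelta(entry_off, unit="D")).year.to_numpy()
    yrs = np.array(sorted(config.uptake_curve))
    clamped = yrs[np.clip(np.searchsorted(yrs, entry_year, side="right") - 1, 0, len(yrs) - 1)]
    base_p = np.array([config.uptake_curve[y] for y in clamped])
    eps = 1e-12
    lp_choice = logit(np.clip(base_p, eps, 1 - eps)) + _lin_pred(zmap, config.choice_log_odds, n)
    initial_study = rng.random(n) < expit(lp_choice)

    # latent clocks, days from entry
    sw_rate = np.exp(_lin_pred(zmap, config.switch_log_hazard, n))
    switch_off = _exponential_times(rng, sw_rate, n)
    cens_off = {
        cause: _exponential_times(rng, config.censor_rates.get(cause, 0.0), n)
        for cause in ("death", "transfer", "cirrhosis")
    }

    # prescription schedule: K potential issues per patient
    K = min(int(np.ceil(horizon / dur)) + 3, 400)
    gaps = np.rint(rng.exponential(config.refill_gap_mean_days, (n, K)))
    stop_draw = rng.random((n, K)) < config.refill_stop_prob
    gap_cum = np.concatenate([np.zeros((n, 1)), np.cumsum(gaps, axis=1)[:, :-1]], axis=1)
    offs = entry_off[:, None] + np.arange(K) * float(dur) + gap_cum  # absolute day offsets

    stop_any = stop_draw.any(axis=1)
    first_stop = np.where(stop_any, stop_draw.argmax(axis=1), K - 1)
    n_persist = first_stop + 1  # issues 0 .. first_stop inclusive

    # switch lands on the first scheduled refill at/after the latent switch time
    thresh = entry_off + switch_off
    at_or_after = offs >= thresh[:, None]
    has_sw = at_or_after.any(axis=1)
    j_sw = np.where(has_sw, at_or_after.argmax(axis=1), K)

    death_abs = entry_off + cens_off["death"]
    transfer_abs = entry_off + cens_off["transfer"]
    rx_bound = np.minimum(np.minimum(death_abs, transfer_abs), horizon + 0.5)

    j_idx = np.arange(K)[None, :]
    pre_outcome_valid = (j_idx < n_persist[:, None]) & (offs < rx_bound[:, None] - 0.0) & (
        offs <= horizon
    )

    sw_issue_off = offs[np.arange(n), np.minimum(j_sw, K - 1)]
    switch_real = (
        (~initial_study)
        & (j_sw < K)
        & (j_sw < n_persist)
        & (sw_issue_off <= horizon)
        & (sw_issue_off < rx_bound)
    )

    # treatment start for the outcome hazard (time-fixed from index)
    s_abs = np.where(initial_study, entry_off, np.where(switch_real, sw_issue_off, np.inf))

    r0 = config.outcome_baseline_rate * np.exp(_lin_pred(zmap, config.confounder_log_hrs, n))
    r1 = r0 * math.exp(config.true_log_hr) if np.isfinite(config.true_log_hr) else r0 * np.exp(
        config.true_log_hr
    )
    e_out = rng.exponential(1.0, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        pre_haz = r0 * np.where(np.isfinite(s_abs), s_abs - entry_off, np.inf)
        pre_haz = np.where(r0 > 0, pre_haz, np.inf)  # rate 0: outcome never before switch
        t_first = entry_off + np.where(r0 > 0, e_out / np.where(r0 > 0, r0, 1.0), np.inf)
        t_second = s_abs + np.where(r1 > 0, (e_out - pre_haz) / np.where(r1 > 0, r1, 1.0), np.inf)
    outcome_abs = np.where(e_out < pre_haz, t_first, t_second)
    outcome_abs = np.rint(outcome_abs)
    # an outcome before the scheduled switch prescription means the switch
    # never materializes (prescribing stops at the outcome)
    switch_real = switch_real & (sw_issue_off < outcome_abs)

    valid = pre_outcome_valid & (offs < outcome_abs[:, None])
    pat_i, iss_j = np.nonzero(valid)
    issue_off = offs[valid]
    is_study_issue = initial_study[pat_i] | (switch_real[pat_i] & (iss_j >= j_sw[pat_i]))

    prescriptions = pd.DataFrame(
        {
            "patient_id": pat_i.astype(np.int64),
            "drug_class": np.where(is_study_issue, STUDY, COMPARATOR),
            "issue_date": start + pd.to_timedelta(issue_off, unit="D"),
            "supply_days": np.full(pat_i.size, dur, dtype=np.int64),
        }
    ).sort_values(["patient_id", "issue_date", "drug_class"], kind="stable", ignore_index=True)

    patients = pd.DataFrame({"patient_id": np.arange(n, dtype=np.int64)})
    patients["registration_date"] = start + pd.to_timedelta(entry_off - lead, unit="D")
    for name, col in raw_cov.items():
        patients[name] = col

    # events: outcome only if observable (before death/transfer) and in-window
    ev_frames = []
    outcome_ok = (
        np.isfinite(outcome_abs)
        & (outcome_abs <= np.minimum(death_abs, transfer_abs))
        & (outcome_abs <= horizon)
    )
    ev_frames.append(
        pd.DataFrame(
            {
                "patient_id": np.flatnonzero(outcome_ok).astype(np.int64),
                "event_type": "outcome",
                "event_date": start + pd.to_timedelta(outcome_abs[outcome_ok], unit="D"),
            }
        )
    )
    for cause in ("death", "transfer", "cirrhosis"):
        abs_t = np.rint(entry_off + cens_off[cause])
        ok = np.isfinite(abs_t) & (abs_t <= horizon)
        ev_frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.flatnonzero(ok).astype(np.int64),
                    "event_type": cause,
                    "event_date": start + pd.to_timedelta(abs_t[ok], unit="D"),
                }
            )
        )
    events = pd.concat(ev_frames, ignore_index=True).sort_values(
        ["patient_id", "event_date", "event_type"], kind="stable", ignore_index=True
    )

    truth_patients = pd.DataFrame(
        {
            "patient_id": np.arange(n, dtype=np.int64),
            "entry_date": start + pd.to_timedelta(entry_off, unit="D"),
            "initial_drug": np.where(initial_study, STUDY, COMPARATOR),
            "latent_switch_day": switch_off,
            "switched": switch_real,
            "switch_date": pd.Series(
                np.where(switch_real, sw_issue_off, np.nan), dtype=float
            ).pipe(lambda s: start + pd.to_timedelta(s, unit="D")),
            "latent_outcome_day": outcome_abs - entry_off,
        }
    )
    truth = {
        "true_log_hr": config.true_log_hr,
        "confounder_log_hrs": dict(config.confounder_log_hrs),
        "choice_log_odds": dict(config.choice_log_odds),
        "seed": config.seed,
        "patients": truth_patients,
    }
    return SyntheticDataset(patients, prescriptions, events, truth)


def generate_confounded_scenario(strength: float, seed: int) -> SimulationConfig:
    """Config in which age and comorbidity drive drug choice, switching
    and the outcome, with coefficient magnitudes scaled by ``strength``.

    ``strength = 0`` yields a randomized-treatment configuration (all
    covariate coefficients zero) with a null treatment effect.
    """
    if strength < 0:
        raise ValueError("strength must be nonnegative")
    s = float(strength)
    # early-adoption uptake: the study drug stays the minority choice, so
    # every treated user faces a comparator pool several times their number
    # (the overlap regime 1:1 ATT matching presumes)
    uptake = {2000: 0.04, 2001: 0.07, 2002: 0.10, 2003: 0.13, 2004: 0.16}
    return SimulationConfig(
        uptake_curve=uptake,
        choice_log_odds={"age": 0.5 * s, "comorbidity": 0.7 * s},
        switch_log_hazard={"intercept": math.log(4e-4), "age": 0.3 * s, "comorbidity": 0.5 * s},
        confounder_log_hrs={"age": 0.5 * s, "comorbidity": 0.7 * s},
        true_log_hr=0.0,
        seed=seed,
    )
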