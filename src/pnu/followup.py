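"""As-treated follow-up, Cox effect estimation and balance diagnostics.

Follow-up runs from each matched person's index date to the earliest of
outcome, study end, death, cirrhosis diagnosis, transfer out of
practice, or treatment discontinuation (end of the continuous treatment
episode containing the index date; a matched comparator is additionally
discontinued at any later switch to the study drug).  Hazard ratios for
the study-vs-comparator contrast come from an unstratified Cox model
with robust (sandwich) standard errors — optionally clustered on
matched pair — fitted overall and separately in the incident and
prevalent new-user subgroups.  Balance between the matched arms is
summarised with absolute standardized mean differences, alongside a
descriptive unmatched comparator group built by sampling one candidate
prescription per exposure set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from pnu.cohort import ROLE_INCIDENT, ROLE_PREVALENT
from pnu.exposure import ExposureSets
from pnu.simulate import COMPARATOR, STUDY

CENSOR_PRECEDENCE = ["outcome", "death", "cirrhosis", "transfer", "discontinuation", "study_end"]


def build_followup(
    pairs: pd.DataFrame,
    episodes: pd.DataFrame,
    events: pd.DataFrame,
    study_end,
) -> pd.DataFrame:
    """Per-person survival interval for every matched individual.

    Returns ``patient_id, arm, pair_id, subgroup, t_stop, event,
    censor_reason`` with ``t_stop`` in days from the index date and
    ``event = 1`` exactly when the earliest cause is the outcome.  Ties
    between causes resolve in the order outcome, death, cirrhosis,
    transfer, discontinuation, study end.  A same-day event yields a
    half-day interval so every record has positive follow-up.
    """
    study_end = pd.Timestamp(study_end)
    long = pd.concat(
        [
            pd.DataFrame(
                {
                    "patient_id": pairs["treated_patient_id"],
                    "arm": STUDY,
                    "index_date": pairs["treated_index_date"],
                    "pair_id": pairs["pair_id"],
                    "subgroup": np.where(
                        pairs["treated_role"] == ROLE_PREVALENT, "prevalent", "incident"
                    ),
                }
            ),
            pd.DataFrame(
                {
                    "patient_id": pairs["comparator_patient_id"],
                    "arm": COMPARATOR,
                    "index_date": pairs["comparator_index_date"],
                    "pair_id": pairs["pair_id"],
                    "subgroup": np.where(
                        pairs["treated_role"] == ROLE_PREVALENT, "prevalent", "incident"
                    ),
                }
            ),
        ],
        ignore_index=True,
    )
    long["index_date"] = pd.to_datetime(long["index_date"])

    epi = episodes.rename(columns={"drug_class": "arm"})
    merged = long.merge(epi, on=["patient_id", "arm"], how="left")
    containing = merged[
        (merged["start_date"] <= merged["index_date"])
        & (merged["index_date"] < merged["episode_end_date"])
    ]
    if len(containing) < len(long):
        missing = long.merge(
            containing[["patient_id", "arm", "pair_id"]],
            on=["patient_id", "arm", "pair_id"],
            how="left",
            indicator=True,
        )
        n_missing = int((missing["_merge"] == "left_only").sum())
        if n_missing:
            raise ValueError(
                f"{n_missing} matched persons have no treatment episode covering "
                "their index date (upstream inconsistency)"
            )
    fu = containing.copy()

    # comparator follow-up also ends at a later switch to the study drug
    study_starts = (
        episodes[episodes["drug_class"] == STUDY]
        .groupby("patient_id")["start_date"]
        .min()
        .rename("first_study_start")
    )
    fu = fu.merge(study_starts, on="patient_id", how="left")
    switch_cut = fu["first_study_start"].where(
        (fu["arm"] == COMPARATOR) & (fu["first_study_start"] > fu["index_date"])
    )
    disc_date = fu["episode_end_date"].where(
        switch_cut.isna(), np.minimum(fu["episode_end_date"], switch_cut)
    )

    if len(events):
        ev = events.pivot_table(
            index="patient_id", columns="event_type", values="event_date", aggfunc="min"
        )
    else:
        ev = pd.DataFrame()
    for cause in ("outcome", "death", "cirrhosis", "transfer"):
        if cause in ev.columns:
            fu[f"_{cause}"] = fu["patient_id"].map(ev[cause])
        else:
            fu[f"_{cause}"] = pd.NaT
        # events strictly before index cannot end follow-up that starts at index
        fu[f"_{cause}"] = fu[f"_{cause}"].where(fu[f"_{cause}"] >= fu["index_date"])

    cause_dates = pd.DataFrame(
        {
            "outcome": fu["_outcome"],
            "death": fu["_death"],
            "cirrhosis": fu["_cirrhosis"],
            "transfer": fu["_transfer"],
            "discontinuation": disc_date,
            "study_end": study_end,
        }
    )[CENSOR_PRECEDENCE]
    end_date = cause_dates.min(axis=1)
    # first cause in precedence order attaining the minimum
    is_min = cause_dates.eq(end_date, axis=0)
    reason = is_min.idxmax(axis=1)

    t_stop = (end_date - fu["index_date"]).dt.days.astype(float)
    t_stop = t_stop.where(t_stop > 0, 0.5)

    out = pd.DataFrame(
        {
            "patient_id": fu["patient_id"],
            "arm": fu["arm"],
            "pair_id": fu["pair_id"],
            "subgroup": fu["subgroup"],
            "index_date": fu["index_date"],
            "t_stop": t_stop,
            "event": (reason == "outcome").astype(int),
            "censor_reason": reason,
        }
    ).reset_index(drop=True)
    return out


@dataclass
class EffectEstimate:
    """Cox hazard-ratio estimate with robust inference for one subgroup."""

    subgroup: str
    log_hr: float
    hr: float
    robust_se: float
    ci95: tuple[float, float]
    confidence_limit_ratio: float
    n_events_study: int
    n_events_comparator: int
    n_persons: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "subgroup": self.subgroup,
            "log_hr": self.log_hr,
            "hr": self.hr,
            "robust_se": self.robust_se,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "confidence_limit_ratio": self.confidence_limit_ratio,
            "n_events_study": self.n_events_study,
            "n_events_comparator": self.n_events_comparator,
            "n_persons": self.n_persons,
            "converged": self.converged,
        }


def fit_cox_robust(
    records: pd.DataFrame,
    subgroup: str = "overall",
    cluster_by_pair: bool = False,
) -> EffectEstimate:
    """Unstratified Cox fit of the treatment indicator with sandwich SE.

    ``subgroup`` selects ``overall``, ``prevalent`` or ``incident``
    records.  With zero events in either arm the estimate is flagged
    non-finite rather than raising.
    """
    if subgroup not in ("overall", "prevalent", "incident"):
        raise ValueError("subgroup must be overall, prevalent or incident")
    df = records if subgroup == "overall" else records[records["subgroup"] == subgroup]
    df = df.assign(treat=(df["arm"] == STUDY).astype(int))
    n_ev_s = int(df.loc[df["treat"] == 1, "event"].sum())
    n_ev_c = int(df.loc[df["treat"] == 0, "event"].sum())
    if n_ev_s == 0 or n_ev_c == 0:
        return EffectEstimate(
            subgroup, np.nan, np.nan, np.nan, (np.nan, np.nan), np.nan, n_ev_s, n_ev_c,
            len(df), False,
        )
    cols = ["t_stop", "event", "treat"] + (["pair_id"] if cluster_by_pair else [])
    fitter = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitter.fit(
            df[cols],
            duration_col="t_stop",
            event_col="event",
            robust=True,
            cluster_col="pair_id" if cluster_by_pair else None,
        )
    beta = float(fitter.params_["treat"])
    se = float(fitter.standard_errors_["treat"])
    lo, hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
    return EffectEstimate(
        subgroup=subgroup,
        log_hr=beta,
        hr=float(np.exp(beta)),
        robust_se=se,
        ci95=(float(lo), float(hi)),
        confidence_limit_ratio=confidence_limit_ratio(lo, hi),
        n_events_study=n_ev_s,
        n_events_comparator=n_ev_c,
        n_persons=len(df),
        converged=True,
    )


def confidence_limit_ratio(low: float, high: float) -> float:
    """Upper over lower 95% confidence bound — a precision summary."""
    if not low > 0:
        raise ValueError("lower confidence limit must be positive")
    if high < low:
        raise ValueError("upper confidence limit below lower")
    return float(high) / float(low)


def smd_from_means(m_a: float, s_a: float, m_b: float, s_b: float) -> float:
    """Continuous standardized difference from group means and SDs."""
    pooled = np.sqrt((s_a**2 + s_b**2) / 2.0)
    diff = abs(m_a - m_b)
    if pooled == 0:
        if diff == 0:
            return 0.0
        warnings.warn("zero pooled variance with unequal means", stacklevel=2)
        return np.inf
    return diff / pooled


def smd_from_counts(x_a: int, n_a: int, x_b: int, n_b: int) -> float:
    """Binary standardized difference from event counts per group."""
    p_a, p_b = x_a / n_a, x_b / n_b
    pooled = np.sqrt((p_a * (1 - p_a) + p_b * (1 - p_b)) / 2.0)
    diff = abs(p_a - p_b)
    if pooled == 0:
        if diff == 0:
            return 0.0
        warnings.warn("zero pooled variance with unequal proportions", stacklevel=2)
        return np.inf
    return diff / pooled


def _smd_categorical(a: np.ndarray, b: np.ndarray) -> float:
    """Mahalanobis-type standardized difference over L-1 level indicators."""
    levels = sorted(map(str, set(a) | set(b)))
    if len(levels) < 2:
        return 0.0
    pa = np.array([(a == lev).mean() for lev in levels[:-1]])
    pb = np.array([(b == lev).mean() for lev in levels[:-1]])
    t = pa - pb
    sa = np.diag(pa) - np.outer(pa, pa)
    sb = np.diag(pb) - np.outer(pb, pb)
    s = (sa + sb) / 2.0
    return float(np.sqrt(t @ np.linalg.pinv(s) @ t))


def standardized_mean_difference(group_a, group_b, kind: str) -> float:
    """Absolute standardized mean difference between two samples.

    ``kind`` is ``continuous`` (pooled-SD standardization), ``binary``
    (pooled proportion variance) or ``categorical`` (multivariate
    Mahalanobis-type difference over level indicators).
    """
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if kind == "continuous":
        return smd_from_means(
            a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1)
        )
    if kind == "binary":
        return smd_from_counts(int(a.sum()), a.size, int(b.sum()), b.size)
    if kind == "categorical":
        return _smd_categorical(a.astype(str), b.astype(str))
    raise ValueError("kind must be continuous, binary or categorical")


def sample_unmatched_group(sets: ExposureSets, seed: int) -> pd.DataFrame:
    """One comparator candidate drawn uniformly per nonempty exposure set.

    This is the descriptive 'unmatched comparator' group used in the
    balance table's first column.
    """
    rng = np.random.default_rng(seed)
    cand = sets.candidates
    if cand.empty:
        return cand.copy()
    key = rng.random(len(cand))
    shuffled = cand.assign(_key=key).sort_values(["set_id", "_key"], kind="stable")
    picked = shuffled.groupby("set_id", sort=True).head(1).drop(columns="_key")
    return picked.reset_index(drop=True)


def balance_table(
    unmatched_sample: pd.DataFrame,
    pairs: pd.DataFrame,
    patients: pd.DataFrame,
    covariates: dict[str, str],
) -> pd.DataFrame:
    """Covariate summaries in the three descriptive groups plus ASD.

    ``covariates`` maps covariate name to its kind.  The ASD column
    compares the two *matched* arms.  Calendar year (kind
    ``categorical``) is resolved from each person's index date when
    requested under the name ``calendar_year``.
    """

    def resolve(frame: pd.DataFrame, id_col: str, date_col: str) -> pd.DataFrame:
        out = frame[[id_col, date_col]].rename(
            columns={id_col: "patient_id", date_col: "index_date"}
        )
        out = out.merge(patients, on="patient_id", how="left")
        out["calendar_year"] = pd.to_datetime(out["index_date"]).dt.year
        return out

    groups = {
        "unmatched_comparator": resolve(
            unmatched_sample, "candidate_patient_id", "candidate_index_date"
        ),
        "matched_comparator": resolve(pairs, "comparator_patient_id", "comparator_index_date"),
        "matched_study": resolve(pairs, "treated_patient_id", "treated_index_date"),
    }

    rows = []
    for name, kind in covariates.items():
        row: dict = {"covariate": name, "kind": kind}
        for gname, g in groups.items():
            vals = g[name]
            if kind == "continuous":
                row[f"{gname}_mean"] = float(vals.mean())
                row[f"{gname}_sd"] = float(vals.std(ddof=1))
            elif kind == "binary":
                row[f"{gname}_mean"] = float(vals.mean())
                row[f"{gname}_sd"] = np.nan
            else:
                row[f"{gname}_mean"] = np.nan
                row[f"{gname}_sd"] = np.nan
        row["absolute_standardized_difference"] = standardized_mean_difference(
            groups["matched_comparator"][name].to_numpy(),
            groups["matched_study"][name].to_numpy(),
            kind,
        )
        row["asd_unmatched"] = standardized_mean_difference(
            groups["unmatched_comparator"][name].to_numpy(),
            groups["matched_study"][name].to_numpy(),
            kind,
        )
        rows.append(row)
    return pd.DataFrame(rows)
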