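"""Base-cohort assembly: new-user classification and treatment episodes.

A patient enters the base cohort at their first prescription of either
drug class inside the study window, provided (i) no prescription of
either class fell in the washout period immediately before it and
(ii) the patient had at least the washout length of registered history.
The entry prescription's class assigns the role: study-drug entrants are
incident new users; comparator entrants are comparator members and, if
they later receive the study drug inside the window, additionally yield
a prevalent new-user (switcher) membership at that first study-drug
date.

Continuous treatment episodes follow the convention
``first issue + supply + successive overlapping supplies + grace``; by
default a refill gap bridged by the grace period keeps the episode
alive (``bridge_gaps=True``), with strict supply overlap available as an
alternative.  Dates are whole days; episode intervals are treated as
half-open ``[start, episode_end)`` for person-time arithmetic.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd

from pnu.simulate import COMPARATOR, STUDY

ROLE_INCIDENT = "incident_study"
ROLE_PREVALENT = "prevalent_study"
ROLE_COMPARATOR = "comparator"


class CohortTables(NamedTuple):
    members: pd.DataFrame
    excluded: pd.DataFrame


def build_treatment_episodes(
    prescriptions: pd.DataFrame,
    grace_days: int = 30,
    bridge_gaps: bool = True,
) -> pd.DataFrame:
    """Merge per-patient, per-class prescriptions into continuous episodes.

    Consecutive prescriptions join one episode when the next issue date
    falls on or before the running supply end (plus ``grace_days`` when
    ``bridge_gaps``).  ``episode_end_date`` is the final supply end plus
    the grace period.

    Returns columns ``patient_id, drug_class, start_date,
    supply_end_date, episode_end_date, n_prescriptions``.
    """
    if grace_days < 0:
        raise ValueError("grace_days must be nonnegative")
    rx = prescriptions.copy()
    if (rx["supply_days"] < 1).any():
        raise ValueError("supply_days must be >= 1 for every prescription")
    rx = rx.sort_values(["patient_id", "drug_class", "issue_date"], kind="stable")
    rx["supply_end"] = rx["issue_date"] + pd.to_timedelta(rx["supply_days"], unit="D")

    grp = rx.groupby(["patient_id", "drug_class"], sort=False)
    run_end = grp["supply_end"].cummax()
    prev_end = run_end.groupby([rx["patient_id"], rx["drug_class"]], sort=False).shift(1)
    allow = pd.to_timedelta(grace_days if bridge_gaps else 0, unit="D")
    new_episode = prev_end.isna() | (rx["issue_date"] > prev_end + allow)
    rx["episode_id"] = np.cumsum(new_episode.to_numpy())

    episodes = (
        rx.groupby("episode_id", sort=True)
        .agg(
            patient_id=("patient_id", "first"),
            drug_class=("drug_class", "first"),
            start_date=("issue_date", "min"),
            supply_end_date=("supply_end", "max"),
            n_prescriptions=("issue_date", "size"),
        )
        .reset_index(drop=True)
    )
    episodes["episode_end_date"] = episodes["supply_end_date"] + pd.to_timedelta(
        grace_days, unit="D"
    )
    return episodes


def classify_new_users(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    window: tuple[str, str] | tuple[pd.Timestamp, pd.Timestamp],
    washout_days: int = 365,
) -> CohortTables:
    """Assign base-cohort memberships and log exclusions.

    Returns ``CohortTables(members, excluded)``.  ``members`` has one row
    per membership with columns ``patient_id, role, entry_date,
    index_date, prior_comparator_rx, time_since_entry_days,
    calendar_year, switch_date``; a switcher contributes both a
    ``comparator`` and a ``prevalent_study`` row.  ``excluded`` lists
    patients removed at entry with a reason code
    (``washout_violation, insufficient_history, missing_registration``).
    """
    if washout_days <= 0:
        raise ValueError("washout_days must be positive")
    start, end = (pd.Timestamp(d) for d in window)
    rx = prescriptions.sort_values(["patient_id", "issue_date"], kind="stable")
    in_win = rx[(rx["issue_date"] >= start) & (rx["issue_date"] <= end)]
    if in_win.empty:
        warnings.warn("study window contains no prescriptions", stacklevel=2)

    entry = in_win.groupby("patient_id", as_index=False)["issue_date"].min()
    entry = entry.rename(columns={"issue_date": "entry_date"})

    # washout: any prescription of either class strictly before entry and
    # within washout_days of it
    pre = rx.merge(entry, on="patient_id")
    pre = pre[pre["issue_date"] < pre["entry_date"]]
    gap = (pre["entry_date"] - pre["issue_date"]).dt.days
    washout_bad = set(pre.loc[gap < washout_days, "patient_id"])

    reg = patients.set_index("patient_id")["registration_date"]
    entry = entry.merge(
        reg.rename("registration_date"), left_on="patient_id", right_index=True, how="left"
    )
    missing_reg = entry["registration_date"].isna()
    hist_days = (entry["entry_date"] - entry["registration_date"]).dt.days
    short_hist = (~missing_reg) & (hist_days < washout_days)

    excluded_rows = []
    for pid in entry.loc[missing_reg, "patient_id"]:
        excluded_rows.append((pid, "missing_registration"))
    for pid in entry.loc[short_hist, "patient_id"]:
        excluded_rows.append((pid, "insufficient_history"))
    for pid in sorted(washout_bad):
        excluded_rows.append((pid, "washout_violation"))
    excluded = pd.DataFrame(excluded_rows, columns=["patient_id", "reason"]).drop_duplicates(
        "patient_id"
    )

    ok = entry[~missing_reg & ~short_hist & ~entry["patient_id"].isin(washout_bad)]
    ok = ok[["patient_id", "entry_date"]]

    win_ok = in_win.merge(ok, on="patient_id")
    # entrant class: a study prescription on the entry date makes the
    # patient a study-drug entrant (same-day tie resolved toward study)
    at_entry = win_ok[win_ok["issue_date"] == win_ok["entry_date"]]
    study_entrants = set(at_entry.loc[at_entry["drug_class"] == STUDY, "patient_id"])

    first_study = (
        win_ok[win_ok["drug_class"] == STUDY].groupby("patient_id")["issue_date"].min()
    )

    is_study_entrant = ok["patient_id"].isin(study_entrants)
    cols = [
        "patient_id",
        "role",
        "entry_date",
        "index_date",
        "prior_comparator_rx",
        "time_since_entry_days",
        "calendar_year",
        "switch_date",
    ]

    incident = ok[is_study_entrant].copy()
    incident["role"] = ROLE_INCIDENT
    incident["index_date"] = incident["entry_date"]
    incident["prior_comparator_rx"] = 0
    incident["time_since_entry_days"] = 0
    incident["calendar_year"] = incident["entry_date"].dt.year
    incident["switch_date"] = pd.NaT

    comp = ok[~is_study_entrant].copy()
    comp["switch_date"] = comp["patient_id"].map(first_study)
    comp["role"] = ROLE_COMPARATOR
    comp["index_date"] = pd.NaT
    comp["prior_comparator_rx"] = 0
    comp["time_since_entry_days"] = 0
    comp["calendar_year"] = comp["entry_date"].dt.year

    switchers = comp[comp["switch_date"].notna()].copy()
    if not switchers.empty:
        counted = win_ok.merge(
            switchers[["patient_id", "switch_date"]], on="patient_id"
        )
        counted = counted[
            (counted["drug_class"] == COMPARATOR)
            & (counted["issue_date"] >= counted["entry_date"])
            & (counted["issue_date"] < counted["switch_date"])
        ]
        k = counted.groupby("patient_id").size()
        switchers["role"] = ROLE_PREVALENT
        switchers["index_date"] = switchers["switch_date"]
        switchers["prior_comparator_rx"] = (
            switchers["patient_id"].map(k).fillna(0).astype(int)
        )
        switchers["time_since_entry_days"] = (
            (switchers["switch_date"] - switchers["entry_date"]).dt.days.astype(int)
        )
        switchers["calendar_year"] = switchers["switch_date"].dt.year

    members_df = pd.concat(
        [incident[cols], comp[cols], switchers[cols] if not switchers.empty else None],
        ignore_index=True,
    )
    if not members_df.empty:
        members_df = members_df.sort_values(
            ["patient_id", "entry_date", "role"], kind="stable", ignore_index=True
        )
    return CohortTables(members_df, excluded)


def prior_rx_count(patient_id, as_of, prescriptions: pd.DataFrame) -> int:
    """Comparator-class prescriptions of ``patient_id`` strictly before ``as_of``."""
    as_of = pd.Timestamp(as_of)
    rx = prescriptions
    mask = (
        (rx["patient_id"] == patient_id)
        & (rx["drug_class"] == COMPARATOR)
        & (rx["issue_date"] < as_of)
    )
    return int(mask.sum())
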