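"""Exposure-set construction for study-drug initiators.

For every study-drug user (incident or prevalent) an exposure set pools
the comparator index prescriptions that look like the treated user's
moment of initiation:

* ``prescription``: candidates with the same number of prior comparator
  prescriptions;
* ``time``: candidates within a caliper (default +/- 30 days, inclusive)
  on the time-since-base-cohort-entry scale;
* ``hybrid``: same prior-prescription count AND within the time caliper
  AND the same calendar year (compared on index dates).

Each comparator prescription from the patient's cohort entry up to (but
excluding) any switch to the study drug is a candidate index, carrying
its own prior-prescription count, time since that patient's entry, and
calendar year.  A comparator patient may therefore appear in many sets
with several distinct candidate prescriptions; uniqueness is enforced at
matching, not here.  Empty sets are retained and flagged so the
match-rate diagnostic keeps its denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pnu.cohort import ROLE_COMPARATOR, ROLE_INCIDENT, ROLE_PREVALENT
from pnu.simulate import COMPARATOR

_KINDS = ("prescription", "time", "hybrid")

CANDIDATE_COLUMNS = [
    "set_id",
    "candidate_patient_id",
    "candidate_index_date",
    "prior_comparator_rx",
    "time_since_entry_days",
    "calendar_year",
]


@dataclass(frozen=True)
class ExposureSetDefinition:
    """Which predicates candidates must satisfy relative to the treated user."""

    kind: str
    caliper_days: int = 30

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.caliper_days < 1:
            raise ValueError("caliper_days must be positive")

    @property
    def uses_caliper(self) -> bool:
        return self.kind in ("time", "hybrid")


@dataclass
class ExposureSets:
    """Treated users and their candidate pools under one definition.

    ``treated``: one row per study-drug user (``set_id`` equals the
    treated patient id, which is unique across study-drug memberships)
    with role, index date, prior count, time since entry and year, plus
    ``n_candidates``.  ``candidates``: the long table of
    (set, candidate prescription) rows.
    """

    treated: pd.DataFrame
    candidates: pd.DataFrame
    definition: ExposureSetDefinition

    @property
    def n_sets(self) -> int:
        return len(self.treated)

    @property
    def empty_sets(self) -> pd.DataFrame:
        return self.treated[self.treated["n_candidates"] == 0]

    def write(self, path: str | Path) -> None:
        self.candidates.to_csv(path, index=False, date_format="%Y-%m-%d")


def candidate_indices_for_comparator(
    members: pd.DataFrame, prescriptions: pd.DataFrame
) -> pd.DataFrame:
    """Candidate index prescriptions for comparator cohort members.

    One row per comparator-class prescription from the member's cohort
    entry up to (excluding) any switch date, with the prior-prescription
    count (strictly earlier comparator prescriptions since entry), days
    since the member's own entry, and calendar year.
    """
    comp = members[members["role"] == ROLE_COMPARATOR][
        ["patient_id", "entry_date", "switch_date"]
    ]
    rx = prescriptions[prescriptions["drug_class"] == COMPARATOR]
    rx = rx.merge(comp, on="patient_id")
    rx = rx[rx["issue_date"] >= rx["entry_date"]]
    rx = rx[rx["switch_date"].isna() | (rx["issue_date"] < rx["switch_date"])]
    rx = rx.sort_values(["patient_id", "issue_date"], kind="stable")
    # strictly-before count: rank handles same-day duplicates correctly
    rx["prior_comparator_rx"] = (
        rx.groupby("patient_id")["issue_date"].rank(method="min").astype(int) - 1
    )
    rx["time_since_entry_days"] = (rx["issue_date"] - rx["entry_date"]).dt.days
    rx["calendar_year"] = rx["issue_date"].dt.year
    out = rx.rename(
        columns={"patient_id": "candidate_patient_id", "issue_date": "candidate_index_date"}
    )
    return out[
        [
            "candidate_patient_id",
            "candidate_index_date",
            "prior_comparator_rx",
            "time_since_entry_days",
            "calendar_year",
        ]
    ].reset_index(drop=True)


def _ranges(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Concatenated aranges [lo_i, hi_i) without a Python loop."""
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    starts_rep = np.repeat(lo, counts)
    offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    return starts_rep + offsets


def _join_time(treated: pd.DataFrame, cand: pd.DataFrame, caliper: int) -> pd.DataFrame:
    """Inclusive-caliper join on time since entry via sorted interval lookup."""
    cand = cand.sort_values("time_since_entry_days", kind="stable", ignore_index=True)
    tse = cand["time_since_entry_days"].to_numpy()
    t = treated["time_since_entry_days"].to_numpy()
    lo = np.searchsorted(tse, t - caliper, side="left")
    hi = np.searchsorted(tse, t + caliper, side="right")
    set_rep = np.repeat(treated["set_id"].to_numpy(), hi - lo)
    out = cand.take(_ranges(lo, hi)).reset_index(drop=True)
    out.insert(0, "set_id", set_rep)
    return out


def _combine_keys(arrays: list[np.ndarray]) -> np.ndarray:
    """Order-preserving composite integer key for (count[, year]) groups."""
    if len(arrays) == 1:
        return arrays[0].astype(np.int64)
    k, year = arrays
    return k.astype(np.int64) * 100_000 + year.astype(np.int64)


def _join_grouped(
    treated: pd.DataFrame,
    cand: pd.DataFrame,
    keys: tuple[str, ...],
    caliper: int | None = None,
) -> pd.DataFrame:
    """Equi-join on ``keys`` with an optional inclusive time caliper."""
    cand_s = cand.sort_values(
        list(keys) + ["time_since_entry_days"], kind="stable", ignore_index=True
    )
    ckey = _combine_keys([cand_s[k].to_numpy() for k in keys])
    tkey = _combine_keys([treated[k].to_numpy() for k in keys])
    blo = np.searchsorted(ckey, tkey, side="left")
    bhi = np.searchsorted(ckey, tkey, side="right")
    if caliper is None:
        lo, hi = blo, bhi
    else:
        tse = cand_s["time_since_entry_days"].to_numpy()
        t_tse = treated["time_since_entry_days"].to_numpy()
        lo = np.empty_like(blo)
        hi = np.empty_like(bhi)
        for i in range(blo.size):
            a, b = blo[i], bhi[i]
            lo[i] = a + np.searchsorted(tse[a:b], t_tse[i] - caliper, side="left")
            hi[i] = a + np.searchsorted(tse[a:b], t_tse[i] + caliper, side="right")
    set_rep = np.repeat(treated["set_id"].to_numpy(), hi - lo)
    out = cand_s.take(_ranges(lo, hi)).reset_index(drop=True)
    out.insert(0, "set_id", set_rep)
    return out


def build_exposure_sets(
    members: pd.DataFrame,
    prescriptions: pd.DataFrame,
    definition: ExposureSetDefinition,
) -> ExposureSets:
    """One exposure set per study-drug user under ``definition``.

    A treated user never appears in their own candidate pool (a
    prevalent new user's earlier comparator prescriptions are excluded
    from their own set).
    """
    treated = members[members["role"].isin([ROLE_INCIDENT, ROLE_PREVALENT])][
        [
            "patient_id",
            "role",
            "index_date",
            "prior_comparator_rx",
            "time_since_entry_days",
            "calendar_year",
        ]
    ].copy()
    treated.insert(0, "set_id", treated["patient_id"])
    treated = treated.rename(columns={"role": "treated_role"})
    cand = candidate_indices_for_comparator(members, prescriptions)

    if definition.kind == "prescription":
        joined = _join_grouped(treated, cand, keys=("prior_comparator_rx",))
    elif definition.kind == "time":
        joined = _join_time(treated, cand, definition.caliper_days)
    else:  # hybrid
        joined = _join_grouped(
            treated,
            cand,
            keys=("prior_comparator_rx", "calendar_year"),
            caliper=definition.caliper_days,
        )

    # a treated user never matches themself (set_id is the treated patient id)
    joined = joined[joined["candidate_patient_id"] != joined["set_id"]]
    joined = joined[CANDIDATE_COLUMNS].reset_index(drop=True)
    sizes = joined["set_id"].value_counts()
    treated["n_candidates"] = treated["set_id"].map(sizes).fillna(0).astype(int)
    treated = treated.sort_values("set_id", kind="stable", ignore_index=True)
    return ExposureSets(treated=treated, candidates=joined, definition=definition)
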