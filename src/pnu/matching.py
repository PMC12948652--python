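"""Positivity screening and chronological 1:1 nearest-TCPS matching.

The positivity check asks, per exposure set and over *all* members (not
only sampled ones), whether the treated user's score lies inside the
inclusive range of the comparator candidates' scores; violating sets
are dropped before matching.

Matching processes treated users in ascending index-date order (ties by
patient id).  Within each surviving set the available candidate with
the smallest absolute score difference is selected; exact ties go to
the earlier candidate index date, then the smaller patient id.
Selection is without replacement at the comparator-person level: once a
comparator patient is matched, all of their candidate prescriptions
become unavailable in every remaining set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REASON_POSITIVITY = "dropped_positivity"
REASON_EMPTY = "empty_set"
REASON_EXHAUSTED = "exhausted_candidates"


def check_positivity(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-set positivity report from the full scored membership table.

    ``scored`` needs columns ``set_id, is_treated, score``.  Returns one
    row per set: ``set_id, treated_score, comparator_score_min,
    comparator_score_max, kept, reason``; a set with no candidates is
    not kept (reason ``no candidates``).
    """
    treated = scored[scored["is_treated"] == 1].set_index("set_id")["score"]
    cand = scored[scored["is_treated"] == 0]
    agg = cand.groupby("set_id")["score"].agg(["min", "max"])
    report = pd.DataFrame({"treated_score": treated})
    report = report.join(agg.rename(columns={"min": "comparator_score_min", "max": "comparator_score_max"}))
    has_cand = report["comparator_score_min"].notna()
    inside = (
        (report["comparator_score_min"] <= report["treated_score"])
        & (report["treated_score"] <= report["comparator_score_max"])
    )
    report["kept"] = has_cand & inside
    report["reason"] = np.where(
        report["kept"], "", np.where(has_cand, "treated score outside range", "no candidates")
    )
    return report.reset_index().rename(columns={"index": "set_id"})


def match_chronological(
    scored: pd.DataFrame,
    positivity: pd.DataFrame,
    treated_info: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy chronological 1:1 match without replacement.

    ``scored`` is the full scored membership table
    (:func:`pnu.tcps.score_all_members` output); ``positivity`` the
    :func:`check_positivity` report; ``treated_info`` is
    ``sets.treated`` (set_id, patient_id, treated_role, index_date, ...).

    Returns ``(pairs, unmatched)``.  ``pairs`` has one row per match
    with both parties' ids, index dates and scores plus a ``pair_id``;
    ``unmatched`` lists treated users without a match and a reason code.
    """
    kept = positivity.set_index("set_id")["kept"]
    empty_reason = positivity.set_index("set_id")["reason"] == "no candidates"

    t = treated_info.merge(
        scored[scored["is_treated"] == 1][["set_id", "score"]], on="set_id", how="left"
    )
    t = t.sort_values(["index_date", "patient_id"], kind="stable")

    cand = scored[scored["is_treated"] == 0]
    by_set: dict = {}
    for set_id, grp in cand.groupby("set_id", sort=False):
        by_set[set_id] = (
            grp["patient_id"].to_numpy(),
            grp["candidate_index_date"].to_numpy(),
            grp["score"].to_numpy(),
        )

    max_pid = int(cand["patient_id"].max()) + 1 if len(cand) else 1
    used = np.zeros(max_pid, dtype=bool)

    pairs, unmatched = [], []
    pair_id = 0
    for row in t.itertuples(index=False):
        set_id = row.set_id
        if empty_reason.get(set_id, False) or set_id not in by_set:
            unmatched.append((set_id, row.patient_id, row.treated_role, REASON_EMPTY))
            continue
        if not kept.get(set_id, False):
            unmatched.append((set_id, row.patient_id, row.treated_role, REASON_POSITIVITY))
            continue
        pids, dates, scores = by_set[set_id]
        avail = ~used[pids]
        if not avail.any():
            unmatched.append((set_id, row.patient_id, row.treated_role, REASON_EXHAUSTED))
            continue
        d = np.abs(scores - row.score)
        d_avail = np.where(avail, d, np.inf)
        dmin = d_avail.min()
        tie = np.flatnonzero(d_avail == dmin)
        # tie-break: earlier candidate index date, then smaller patient id
        order = np.lexsort((pids[tie], dates[tie]))
        j = tie[order[0]]
        used[pids[j]] = True
        pairs.append(
            dict(
                pair_id=pair_id,
                set_id=set_id,
                treated_patient_id=row.patient_id,
                treated_index_date=row.index_date,
                treated_role=row.treated_role,
                treated_score=row.score,
                comparator_patient_id=pids[j],
                comparator_index_date=dates[j],
                comparator_score=scores[j],
            )
        )
        pair_id += 1

    pairs_df = pd.DataFrame(
        pairs,
        columns=[
            "pair_id",
            "set_id",
            "treated_patient_id",
            "treated_index_date",
            "treated_role",
            "treated_score",
            "comparator_patient_id",
            "comparator_index_date",
            "comparator_score",
        ],
    )
    unmatched_df = pd.DataFrame(
        unmatched, columns=["set_id", "treated_patient_id", "treated_role", "reason"]
    )
    return pairs_df, unmatched_df


def match_rate(pairs: pd.DataFrame, treated_info: pd.DataFrame) -> dict:
    """Matched proportion overall and by treated role."""
    out = {"overall": len(pairs) / len(treated_info) if len(treated_info) else np.nan}
    for role, grp in treated_info.groupby("treated_role"):
        n_matched = int((pairs["treated_role"] == role).sum()) if len(pairs) else 0
        out[role] = n_matched / len(grp)
    return out
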