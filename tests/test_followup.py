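"""As-treated follow-up, Cox estimation, balance arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest

from pnu.followup import (
    build_followup,
    confidence_limit_ratio,
    fit_cox_robust,
    sample_unmatched_group,
    smd_from_counts,
    smd_from_means,
    standardized_mean_difference,
)
from pnu.simulate import COMPARATOR, STUDY

from conftest import day, make_sets


def pairs_frame(rows):
    """Rows of (pair_id, treated_pid, treated_day, role, comp_pid, comp_day)."""
    return pd.DataFrame(
        [
            {
                "pair_id": pid,
                "set_id": pid,
                "treated_patient_id": t,
                "treated_index_date": day(td),
                "treated_role": role,
                "treated_score": 0.5,
                "comparator_patient_id": c,
                "comparator_index_date": day(cd),
                "comparator_score": 0.5,
            }
            for pid, t, td, role, c, cd in rows
        ]
    )


def episode_frame(rows):
    """Rows of (patient_id, drug_class, start_day, supply_end_day, episode_end_day)."""
    return pd.DataFrame(
        [
            {
                "patient_id": p,
                "drug_class": d,
                "start_date": day(s),
                "supply_end_date": day(se),
                "episode_end_date": day(e),
            }
            for p, d, s, se, e in rows
        ]
    )


def events_frame(rows):
    return pd.DataFrame(
        [
            {"patient_id": p, "event_type": t, "event_date": day(d)}
            for p, t, d in rows
        ]
    )


BASIC_EPISODES = episode_frame(
    [(1, STUDY, 0, 28, 58), (2, COMPARATOR, 0, 28, 58)]
)
BASIC_PAIRS = pairs_frame([(0, 1, 0, "incident_study", 2, 0)])


@pytest.mark.parametrize(
    "events, expect",
    [
        ([], (58.0, "discontinuation", 0)),
        ([(1, "outcome", 30)], (30.0, "outcome", 1)),
        ([(1, "death", 40)], (40.0, "death", 0)),
        ([(1, "death", 40), (1, "outcome", 30)], (30.0, "outcome", 1)),
    ],
)
def test_earliest_censoring_cause_wins(events, expect):
    fu = build_followup(BASIC_PAIRS, BASIC_EPISODES, events_frame(events), day(2000))
    row = fu[fu["arm"] == STUDY].iloc[0]
    assert (row["t_stop"], row["censor_reason"], row["event"]) == expect


def test_study_end_censors_before_discontinuation():
    fu = build_followup(BASIC_PAIRS, BASIC_EPISODES, events_frame([]), day(40))
    assert (fu["t_stop"] == 40.0).all()
    assert (fu["censor_reason"] == "study_end").all()


def test_comparator_censored_at_later_switch_to_study_drug():
    episodes = episode_frame(
        [(1, STUDY, 0, 28, 58), (2, COMPARATOR, 0, 28, 58), (2, STUDY, 20, 48, 78)]
    )
    fu = build_followup(BASIC_PAIRS, episodes, events_frame([]), day(2000))
    comp = fu[fu["arm"] == COMPARATOR].iloc[0]
    assert comp["t_stop"] == 20.0
    assert comp["censor_reason"] == "discontinuation"


def test_same_day_event_yields_half_day_interval():
    fu = build_followup(
        BASIC_PAIRS, BASIC_EPISODES, events_frame([(1, "outcome", 0)]), day(2000)
    )
    row = fu[fu["arm"] == STUDY].iloc[0]
    assert row["t_stop"] == 0.5 and row["event"] == 1


def test_index_outside_any_episode_raises():
    episodes = episode_frame([(1, STUDY, 100, 128, 158), (2, COMPARATOR, 0, 28, 58)])
    with pytest.raises(ValueError, match="no treatment episode"):
        build_followup(BASIC_PAIRS, episodes, events_frame([]), day(2000))


def test_censor_reasons_are_exclusive_and_exhaustive():
    pairs = pairs_frame(
        [(i, 10 + i, 0, "incident_study", 50 + i, 0) for i in range(4)]
    )
    episodes = episode_frame(
        [(10 + i, STUDY, 0, 28, 58) for i in range(4)]
        + [(50 + i, COMPARATOR, 0, 28, 58) for i in range(4)]
    )
    events = events_frame([(10, "outcome", 10), (51, "death", 5), (12, "cirrhosis", 7)])
    fu = build_followup(pairs, episodes, events, day(40))
    assert (fu["t_stop"] > 0).all()
    assert fu["censor_reason"].value_counts().sum() == len(fu)
    assert ((fu["event"] == 1) == (fu["censor_reason"] == "outcome")).all()


def cox_partial_loglik_grid(t, e, x, grid):
    """Explicit Breslow partial log-likelihood evaluated on a beta grid."""
    t, e, x = map(np.asarray, (t, e, x))
    lls = np.zeros(len(grid))
    for i, b in enumerate(grid):
        ll = 0.0
        for j in np.flatnonzero(e):
            risk = t >= t[j]
            ll += b * x[j] - math.log(np.sum(np.exp(b * x[risk])))
        lls[i] = ll
    return lls


def records(rows):
    return pd.DataFrame(
        [
            {
                "patient_id": i,
                "arm": arm,
                "pair_id": i // 2,
                "subgroup": "incident",
                "t_stop": float(t),
                "event": ev,
            }
            for i, (arm, t, ev) in enumerate(rows)
        ]
    )


def test_symmetric_event_patterns_give_null_hazard_ratio():
    rows = []
    for t, ev in [(5, 1), (8, 0), (12, 1), (20, 0), (30, 1)]:
        rows.append((STUDY, t, ev))
        rows.append((COMPARATOR, t, ev))  # identical pattern per arm
    est = fit_cox_robust(records(rows))
    assert est.log_hr == pytest.approx(0.0, abs=1e-6)


def test_cox_mle_matches_partial_likelihood_grid_search(rng):
    rows = []
    for i in range(18):
        arm = STUDY if i % 2 == 0 else COMPARATOR
        t = float(rng.exponential(50) + i * 0.01)  # distinct times
        rows.append((arm, t, int(rng.random() < 0.7)))
    df = records(rows)
    est = fit_cox_robust(df)
    x = (df["arm"] == STUDY).astype(float).to_numpy()
    grid = np.arange(-3.0, 3.0, 1e-4)
    lls = cox_partial_loglik_grid(df["t_stop"], df["event"], x, grid)
    best = grid[int(np.argmax(lls))]
    assert est.log_hr == pytest.approx(best, abs=1e-4)
    # score at the maximizer is ~0
    h = 1e-5
    fd = (
        cox_partial_loglik_grid(df["t_stop"], df["event"], x, [est.log_hr + h])[0]
        - cox_partial_loglik_grid(df["t_stop"], df["event"], x, [est.log_hr - h])[0]
    ) / (2 * h)
    assert abs(fd) < 1e-3


def test_zero_events_in_an_arm_flagged_not_crashed():
    rows = [(STUDY, 10.0, 0), (STUDY, 20.0, 0), (COMPARATOR, 5.0, 1), (COMPARATOR, 8.0, 1)]
    est = fit_cox_robust(records(rows))
    assert not est.converged
    assert math.isnan(est.log_hr)


def test_pair_clustered_robust_variance_runs(rng):
    rows = []
    for i in range(40):
        arm = STUDY if i % 2 == 0 else COMPARATOR
        rows.append((arm, float(rng.exponential(50) + 1), int(rng.random() < 0.5)))
    est = fit_cox_robust(records(rows), cluster_by_pair=True)
    assert est.robust_se > 0
    assert est.ci95[0] < est.hr < est.ci95[1]


@pytest.mark.parametrize(
    "lo, hi, expected",
    [(0.73, 1.35, 1.85), (0.66, 2.55, 3.86), (1.1, 1.1, 1.0)],
)
def test_confidence_limit_ratio_values(lo, hi, expected):
    assert round(confidence_limit_ratio(lo, hi), 2) == expected


def test_confidence_limit_ratio_rejects_nonpositive_or_reversed():
    with pytest.raises(ValueError):
        confidence_limit_ratio(0.0, 1.0)
    with pytest.raises(ValueError):
        confidence_limit_ratio(1.5, 1.0)


def test_smd_reproduces_published_summary_arithmetic():
    assert round(smd_from_means(69.64, 11.85, 69.58, 11.91), 3) == 0.005
    assert round(smd_from_counts(10543, 33065, 10625, 33065), 3) == 0.005


def test_smd_identical_groups_zero_and_zero_variance_flagged():
    x = np.array([1.0, 2.0, 3.0])
    assert standardized_mean_difference(x, x, "continuous") == 0.0
    with pytest.warns(UserWarning):
        v = smd_from_means(1.0, 0.0, 2.0, 0.0)
    assert np.isinf(v)


def test_smd_categorical_two_levels_agrees_with_binary(rng):
    a = rng.integers(0, 2, 500)
    b = rng.integers(0, 2, 500)
    cat = standardized_mean_difference(a.astype(str), b.astype(str), "categorical")
    binary = standardized_mean_difference(a, b, "binary")
    assert cat == pytest.approx(binary, rel=1e-6)


def test_unmatched_sample_one_per_nonempty_set_reproducible():
    sets = make_sets(
        [
            (
                s,
                dict(patient_id=1000 + s, index_day=0, year=2000),
                [dict(patient_id=10 * s + i, index_day=i, year=2000) for i in range(3)],
            )
            for s in range(100)
        ]
        + [(900, dict(patient_id=999, index_day=0, year=2000), [])]
    )
    a = sample_unmatched_group(sets, seed=4)
    b = sample_unmatched_group(sets, seed=4)
    assert len(a) == 100
    pd.testing.assert_frame_equal(a, b)
    single = make_sets(
        [(0, dict(patient_id=99, index_day=0, year=2000), [dict(patient_id=7, index_day=0, year=2000)])]
    )
    for seed in range(5):
        assert sample_unmatched_group(single, seed).iloc[0]["candidate_patient_id"] == 7
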