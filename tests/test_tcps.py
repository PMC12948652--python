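"""Weighted conditional-logit likelihood, sampling and prediction."""

import math

import numpy as np
import pandas as pd
import pytest

from pnu.tcps import (
    ConditionalLogitTCPS,
    SamplingPlan,
    conditional_loglik,
    conditional_loglik_grad,
    fit_tcps,
    predict_tcps,
    sample_within_sets,
)

from conftest import make_sets


def brute_loglik(beta, rows):
    """Term-by-term enumeration of the weighted conditional likelihood.

    ``rows``: list of (set_id, is_treated, x_vector, weight).
    """
    beta = np.asarray(beta, float)
    by_set = {}
    for set_id, is_treated, x, w in rows:
        by_set.setdefault(set_id, []).append((is_treated, np.asarray(x, float), w))
    total = 0.0
    for members in by_set.values():
        treated = [m for m in members if m[0] == 1]
        comparators = [m for m in members if m[0] == 0]
        if len(treated) != 1 or not comparators:
            continue
        eta_t = float(treated[0][1] @ beta)
        denom = math.exp(eta_t)
        for _, x, w in comparators:
            denom += w * math.exp(float(x @ beta))
        total += eta_t - math.log(denom)
    return total


def rows_to_arrays(rows):
    X = np.array([x for _, _, x, _ in rows], float)
    set_ids = np.array([s for s, _, _, _ in rows])
    is_treated = np.array([t for _, t, _, _ in rows])
    weights = np.array([w for _, _, _, w in rows], float)
    return X, set_ids, is_treated, weights


def test_single_set_symmetric_loglik_values():
    rows = [(0, 1, [1.0], 1.0), (0, 0, [0.0], 1.0)]
    assert conditional_loglik([0.0], *rows_to_arrays(rows)) == pytest.approx(
        math.log(0.5)
    )
    rows_w = [(0, 1, [1.0], 1.0), (0, 0, [0.0], 2.0)]
    assert conditional_loglik([0.0], *rows_to_arrays(rows_w)) == pytest.approx(
        math.log(1.0 / 3.0)
    )


def random_instance(rng, n_sets=3, max_rows=4, p=2):
    rows = []
    for s in range(n_sets):
        n = rng.integers(2, max_rows + 1)
        for i in range(n):
            rows.append(
                (
                    s,
                    1 if i == 0 else 0,
                    rng.normal(size=p).tolist(),
                    1.0 if i == 0 else float(rng.integers(1, 5)),
                )
            )
    return rows


def test_loglik_and_gradient_match_enumeration_and_finite_differences(rng):
    for _ in range(25):
        rows = random_instance(rng)
        beta = rng.normal(size=2)
        args = rows_to_arrays(rows)
        assert conditional_loglik(beta, *args) == pytest.approx(
            brute_loglik(beta, rows), abs=1e-10
        )
        grad = conditional_loglik_grad(beta, *args)
        h = 1e-6
        for j in range(2):
            e = np.zeros(2)
            e[j] = h
            fd = (brute_loglik(beta + e, rows) - brute_loglik(beta - e, rows)) / (2 * h)
            assert grad[j] == pytest.approx(fd, abs=1e-5)


def test_mle_matches_grid_search_on_single_binary_covariate(rng):
    rows = []
    true_beta = 0.8
    for s in range(300):
        xs = rng.integers(0, 2, size=5).astype(float)
        probs = np.exp(true_beta * xs)
        treated_idx = rng.choice(5, p=probs / probs.sum())
        for i, x in enumerate(xs):
            rows.append((s, 1 if i == treated_idx else 0, [x], 1.0))
    args = rows_to_arrays(rows)
    model = fit_tcps(*args)
    assert model.converged_
    grid = np.arange(-3.0, 3.0, 1e-4)
    lls = [brute_loglik([b], rows) for b in grid[:: 100]]
    coarse = grid[::100][int(np.argmax(lls))]
    fine = np.arange(coarse - 0.02, coarse + 0.02, 1e-4)
    best = fine[int(np.argmax([brute_loglik([b], rows) for b in fine]))]
    assert model.coef_[0] == pytest.approx(best, abs=1e-4)


def test_identical_covariates_give_zero_coefficient():
    rows = [(s, 1 - i, [1.0, 2.0], 1.0) for s in range(5) for i in range(3)]
    model = fit_tcps(*rows_to_arrays(rows))
    assert np.allclose(model.coef_, 0.0)


def test_perfect_separation_flagged_and_finite_under_ridge(rng):
    rows = []
    for s in range(30):
        rows.append((s, 1, [1.0], 1.0))
        rows.append((s, 0, [0.0], 1.0))
    model = fit_tcps(*rows_to_arrays(rows))
    assert not model.converged_
    assert model.separation_
    assert np.all(np.isfinite(model.coef_))


def test_loglik_concave_hessian_negative_semidefinite(rng):
    import pnu.tcps as T

    rows = random_instance(rng, n_sets=6, max_rows=5, p=3)
    X, set_ids, is_treated, weights = rows_to_arrays(rows)
    Xp, sid, it, w, st, en = T._prepare(X, set_ids, is_treated, weights)
    for _ in range(10):
        beta = rng.normal(size=3) * 2
        _, _, hess = T._loglik_parts(beta, Xp, it, w, st, en)
        eig = np.linalg.eigvalsh(hess)
        assert eig.max() <= 1e-8


def test_parameter_recovery_at_two_thousand_sets(rng):
    true_beta = np.array([0.7, -0.4])
    rows = []
    for s in range(2000):
        xs = rng.normal(size=(8, 2))
        eta = xs @ true_beta
        probs = np.exp(eta - eta.max())
        treated_idx = rng.choice(8, p=probs / probs.sum())
        for i in range(8):
            rows.append((s, 1 if i == treated_idx else 0, xs[i].tolist(), 1.0))
    X, set_ids, is_treated, weights = rows_to_arrays(rows)
    model = fit_tcps(X, set_ids, is_treated, weights)
    assert model.converged_
    import pnu.tcps as T

    Xp, sid, it, w, st, en = T._prepare(X, set_ids, is_treated, weights)
    _, _, hess = T._loglik_parts(model.coef_, Xp, it, w, st, en)
    se = np.sqrt(np.diag(np.linalg.inv(-hess)))
    assert np.all(np.abs(model.coef_ - true_beta) < 3 * se)


def test_matches_statsmodels_conditional_logit(rng):
    sm = pytest.importorskip("statsmodels.api")
    from statsmodels.discrete.conditional_models import ConditionalLogit

    rows = random_instance(rng, n_sets=40, max_rows=5, p=2)
    rows = [(s, t, x, 1.0) for s, t, x, _ in rows]  # unweighted comparison
    X, set_ids, is_treated, weights = rows_to_arrays(rows)
    model = fit_tcps(X, set_ids, is_treated, weights)
    res = ConditionalLogit(is_treated, X, groups=set_ids).fit(disp=0)
    assert np.allclose(model.coef_, res.params, atol=1e-5)


def _three_sets():
    return make_sets(
        [
            (
                0,
                dict(patient_id=100, index_day=10, year=2000),
                [dict(patient_id=i, index_day=i, year=2000) for i in range(10)],
            ),
            (
                1,
                dict(patient_id=101, index_day=20, year=2000),
                [dict(patient_id=20 + i, index_day=i, year=2000) for i in range(4)],
            ),
            (2, dict(patient_id=102, index_day=30, year=2000), []),
        ]
    )


def test_sampling_fraction_and_weights_arithmetic():
    sets = make_sets(
        [
            (
                0,
                dict(patient_id=9999, index_day=0, year=2000),
                [dict(patient_id=i, index_day=0, year=2000) for i in range(1000)],
            )
        ]
    )
    stacked = sample_within_sets(sets, SamplingPlan(target_per_set=50, seed=0))
    cand = stacked[stacked["is_treated"] == 0]
    assert len(cand) == 50
    assert np.allclose(cand["weight"], 20.0)  # 1 / f = 1000 / 50
    treated = stacked[stacked["is_treated"] == 1]
    assert len(treated) == 1 and treated.iloc[0]["weight"] == 1.0


def test_small_set_kept_whole_with_unit_weight():
    sets = _three_sets()
    stacked = sample_within_sets(sets, SamplingPlan(target_per_set=50, seed=0))
    cand = stacked[stacked["is_treated"] == 0]
    assert len(cand) == 14  # all 10 + 4 candidates kept
    assert np.allclose(cand["weight"], 1.0)
    # empty set keeps its treated-only row
    assert (stacked[stacked["set_id"] == 2]["is_treated"] == 1).all()


def test_sampling_reproducible_and_without_replacement(rng):
    sets = make_sets(
        [
            (
                0,
                dict(patient_id=9999, index_day=0, year=2000),
                [dict(patient_id=i, index_day=0, year=2000) for i in range(200)],
            )
        ]
    )
    a = sample_within_sets(sets, SamplingPlan(target_per_set=20, seed=5))
    b = sample_within_sets(sets, SamplingPlan(target_per_set=20, seed=5))
    pd.testing.assert_frame_equal(a, b)
    cand = a[a["is_treated"] == 0]
    assert cand["patient_id"].is_unique


def test_global_fraction_mode_keeps_at_least_one():
    sets = _three_sets()
    stacked = sample_within_sets(
        sets, SamplingPlan(seed=1, mode="global", global_fraction=0.01)
    )
    counts = (
        stacked[stacked["is_treated"] == 0].groupby("set_id").size().reindex([0, 1])
    )
    assert (counts.fillna(0) >= 1).all()
    assert np.allclose(stacked[stacked["is_treated"] == 0]["weight"], 100.0)


def test_beta_zero_scores_one_half_and_saturation_is_stable():
    model = ConditionalLogitTCPS()
    model.coef_ = np.zeros(2)
    assert np.allclose(predict_tcps(model, np.random.randn(5, 2)), 0.5)
    model.coef_ = np.array([1000.0, 0.0])
    scores = predict_tcps(model, np.array([[1.0, 0.0], [-1.0, 0.0]]))
    assert scores[0] == pytest.approx(1.0)
    assert scores[1] == pytest.approx(0.0)
    assert np.all(np.isfinite(scores))


def test_set_constant_column_coefficient_pinned_to_zero(rng):
    rows = random_instance(rng, n_sets=30, max_rows=5, p=1)
    X, set_ids, is_treated, weights = rows_to_arrays(rows)
    const = np.array([(s % 3) * 1.0 for s in set_ids])[:, None]  # constant per set
    X2 = np.hstack([X, const])
    model = fit_tcps(X2, set_ids, is_treated, weights)
    assert model.coef_[1] == 0.0
    assert model.uninformative_[1]
    base = fit_tcps(X, set_ids, is_treated, weights)
    assert model.coef_[0] == pytest.approx(base.coef_[0], abs=1e-10)


def test_nonfinite_design_raises():
    X = np.array([[1.0], [np.nan]])
    with pytest.raises(ValueError):
        fit_tcps(X, np.array([0, 0]), np.array([1, 0]), np.array([1.0, 1.0]))


def test_invalid_sampling_plans_rejected():
    with pytest.raises(ValueError):
        SamplingPlan(target_per_set=0)
    with pytest.raises(ValueError):
        SamplingPlan(mode="global")
    with pytest.raises(ValueError):
        SamplingPlan(mode="bootstrap")
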