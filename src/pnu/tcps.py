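"""Time-conditional propensity scores (TCPS).

The TCPS is the probability of receiving the study drug given
covariates, estimated *conditionally on exposure set*: the stacked data
contain, per set, the treated user's row and a random sample of that
set's comparator candidates, and a conditional logistic model for
treatment is fitted across sets.  Sampling is proportional to set size
(per-set fraction ``f = min(1, target / size)``), and each sampled
comparator row carries weight ``1/f`` so large sets are represented
without being under-counted.  Weights enter the conditional likelihood
in the denominator sum over comparators (the treated row, always
retained, has weight 1):

    ll(beta) = sum_s [ eta_t(s) - log( exp(eta_t(s)) + sum_j w_j exp(eta_j) ) ]

with ``eta = x . beta``.  This weighted pseudo-likelihood is isolated in
:func:`conditional_loglik` so an alternative weight placement can be
substituted in one place.  The fitted model predicts a score
``logistic(x . beta)`` for *every* member of every set, sampled or not.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from pnu.exposure import ExposureSets

logger = logging.getLogger(__name__)


@dataclass
class SamplingPlan:
    """Within-set comparator sampling: how many rows, and with what weight.

    ``per_set`` mode draws ``min(size, target_per_set)`` candidates per
    set (fraction ``f = min(1, target/size)``, weight ``1/f``);
    ``global`` mode applies one fixed ``global_fraction`` to every set
    (at least one candidate is kept per nonempty set).
    """

    target_per_set: int = 50
    seed: int = 0
    mode: str = "per_set"
    global_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.target_per_set < 1:
            raise ValueError("target_per_set must be positive")
        if self.mode not in ("per_set", "global"):
            raise ValueError("mode must be 'per_set' or 'global'")
        if self.mode == "global":
            if self.global_fraction is None or not 0 < self.global_fraction <= 1:
                raise ValueError("global mode needs global_fraction in (0, 1]")


def sample_within_sets(sets: ExposureSets, plan: SamplingPlan) -> pd.DataFrame:
    """Stack treated rows (weight 1) with sampled comparator rows (weight 1/f).

    Returns columns ``set_id, patient_id, index_date, calendar_year,
    is_treated, weight``.  Reproducible given ``plan.seed``.  Sets with
    no candidates contribute a treated-only row (flagged by the set's
    ``n_candidates`` being 0 in ``sets.treated``); they add nothing to
    the conditional likelihood.
    """
    rng = np.random.default_rng(plan.seed)
    cand = sets.candidates
    key = rng.random(len(cand))
    set_codes, _ = pd.factorize(cand["set_id"], sort=True)
    order = np.lexsort((key, set_codes))
    codes_sorted = set_codes[order]
    counts = np.bincount(codes_sorted, minlength=set_codes.max() + 1 if len(cand) else 0)
    group_sizes = counts[codes_sorted]
    starts = np.cumsum(counts) - counts
    rank = np.arange(len(cand)) - starts[codes_sorted]
    if plan.mode == "per_set":
        m = np.minimum(group_sizes, plan.target_per_set)
        weight = group_sizes / m
    else:
        f = plan.global_fraction
        m = np.maximum(1, np.rint(f * group_sizes)).astype(int)
        weight = np.full(group_sizes.shape, 1.0 / f)
    take = rank < m
    sampled = cand.take(order[take])[
        ["set_id", "candidate_patient_id", "candidate_index_date", "calendar_year"]
    ]
    sampled = sampled.rename(
        columns={"candidate_patient_id": "patient_id", "candidate_index_date": "index_date"}
    )
    sampled["is_treated"] = 0
    sampled["weight"] = weight[take]

    treated = sets.treated[["set_id", "patient_id", "index_date", "calendar_year"]].copy()
    treated["is_treated"] = 1
    treated["weight"] = 1.0

    stacked = pd.concat([treated, sampled], ignore_index=True)
    return stacked.sort_values(
        ["set_id", "is_treated", "patient_id", "index_date"],
        ascending=[True, False, True, True],
        kind="stable",
        ignore_index=True,
    )


class CovariateEncoder:
    """Design-matrix encoding shared between fitting and prediction.

    Continuous covariates are standardized by the mean/sd seen at fit
    time; binary covariates enter as 0/1; categorical covariates are
    one-hot encoded against the first level as reference with missing
    values as an explicit ``"missing"`` level; calendar year (taken from
    the row's index date) is treated as categorical when requested.
    """

    def __init__(
        self,
        continuous: tuple[str, ...] = (),
        binary: tuple[str, ...] = (),
        categorical: tuple[str, ...] = (),
        include_calendar_year: bool = True,
    ) -> None:
        self.continuous = tuple(continuous)
        self.binary = tuple(binary)
        self.categorical = tuple(categorical)
        self.include_calendar_year = include_calendar_year

    def fit(self, df: pd.DataFrame) -> "CovariateEncoder":
        self.means_ = {c: float(df[c].mean()) for c in self.continuous}
        self.sds_ = {c: float(df[c].std(ddof=0)) or 1.0 for c in self.continuous}
        self.levels_ = {}
        for c in self.categorical:
            vals = df[c].astype(object).where(df[c].notna(), "missing")
            self.levels_[c] = sorted(map(str, set(vals)))
        if self.include_calendar_year:
            self.levels_["calendar_year"] = sorted(map(str, set(df["calendar_year"])))
        return self

    def transform(self, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        cols, names = [], []
        for c in self.continuous:
            cols.append((df[c].to_numpy(float) - self.means_[c]) / self.sds_[c])
            names.append(c)
        for c in self.binary:
            cols.append(df[c].to_numpy(float))
            names.append(c)
        cat_items = list(self.categorical)
        if self.include_calendar_year:
            cat_items.append("calendar_year")
        for c in cat_items:
            vals = df[c].astype(object).where(df[c].notna(), "missing").map(str)
            for lev in self.levels_[c][1:]:
                cols.append((vals == lev).to_numpy(float))
                names.append(f"{c}[{lev}]")
        X = np.column_stack(cols) if cols else np.empty((len(df), 0))
        return X, names

    def fit_transform(self, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        return self.fit(df).transform(df)


def _group_index(set_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boundaries of contiguous set blocks in an array sorted by set."""
    _, starts = np.unique(set_ids, return_index=True)
    starts = np.sort(starts)
    return starts, np.append(starts[1:], set_ids.size)


def _prepare(X, set_ids, is_treated, weights):
    X = np.asarray(X, float)
    if not np.all(np.isfinite(X)):
        bad = np.flatnonzero(~np.isfinite(X).all(axis=0))
        raise ValueError(f"non-finite values in design columns {bad.tolist()}")
    set_ids = np.asarray(set_ids)
    is_treated = np.asarray(is_treated).astype(bool)
    weights = np.where(is_treated, 1.0, np.asarray(weights, float))
    order = np.lexsort((~is_treated, set_ids))
    X, set_ids, is_treated, weights = (
        X[order],
        set_ids[order],
        is_treated[order],
        weights[order],
    )
    starts, ends = _group_index(set_ids)
    # informative sets: exactly one treated row and at least one comparator
    n_treated = np.add.reduceat(is_treated.astype(int), starts)
    sizes = ends - starts
    keep = (n_treated == 1) & (sizes >= 2)
    row_keep = np.repeat(keep, sizes)
    X, set_ids, is_treated, weights = (
        X[row_keep],
        set_ids[row_keep],
        is_treated[row_keep],
        weights[row_keep],
    )
    starts, ends = _group_index(set_ids)
    return X, set_ids, is_treated, weights, starts, ends


def _loglik_parts(beta, X, is_treated, weights, starts, ends, order=2):
    """Weighted conditional log-likelihood, gradient and Hessian."""
    eta = X @ beta
    sizes = ends - starts
    grp = np.repeat(np.arange(starts.size), sizes)
    m = np.full(starts.size, -np.inf)
    np.maximum.at(m, grp, eta)
    a = weights * np.exp(eta - m[grp])
    denom = np.add.reduceat(a, starts)
    eta_t = eta[is_treated]
    ll = float(np.sum(eta_t - (m + np.log(denom))))
    if order == 0:
        return ll, None, None
    p = a / denom[grp]
    resid = is_treated.astype(float) - p
    grad = X.T @ resid
    if order == 1:
        return ll, grad, None
    Xp = X * p[:, None]
    xbar = np.add.reduceat(Xp, starts, axis=0)
    hess = -(X.T @ Xp - xbar.T @ xbar)
    return ll, grad, hess


class ConditionalLogitTCPS:
    """Weighted exposure-set-conditional logistic model, fitted by Newton.

    Fitted attributes: ``coef_`` (by design column), ``converged_``,
    ``loglik_``, ``n_sets_used_``, ``separation_``, ``loglik_path_``
    (monotone non-decreasing across iterations).
    """

    def __init__(
        self,
        ridge: float = 0.0,
        tol: float = 1e-8,
        max_iter: int = 100,
        separation_ridge: float = 1e-6,
    ) -> None:
        if ridge < 0:
            raise ValueError("ridge must be nonnegative")
        self.ridge = ridge
        self.tol = tol
        self.max_iter = max_iter
        self.separation_ridge = separation_ridge

    def fit(self, X, set_ids, is_treated, weights) -> "ConditionalLogitTCPS":
        X, set_ids, is_treated, weights, starts, ends = _prepare(
            X, set_ids, is_treated, weights
        )
        self.n_sets_used_ = starts.size
        # columns constant within every set (e.g. calendar year under the
        # hybrid definition) carry no conditional information: their
        # coefficients are pinned to zero rather than left to drift
        _, _, h0 = _loglik_parts(np.zeros(X.shape[1]), X, is_treated, weights, starts, ends)
        diag = np.diag(-h0)
        active = diag > 1e-10 * max(1.0, diag.max() if diag.size else 1.0)
        self.uninformative_ = ~active
        Xa = X[:, active]

        beta_a, self.converged_, self.loglik_, self.loglik_path_ = self._newton(
            Xa, is_treated, weights, starts, ends, self.ridge
        )
        self.separation_ = False
        if not self.converged_ and self.ridge == 0 and self.separation_ridge > 0:
            # unbounded likelihood (separation): return the finite ridge maximizer
            self.separation_ = True
            logger.warning(
                "conditional logit did not converge at ridge 0; refitting with "
                "ridge %.1e (possible separation)",
                self.separation_ridge,
            )
            beta_a, _, self.loglik_, self.loglik_path_ = self._newton(
                Xa, is_treated, weights, starts, ends, self.separation_ridge
            )
        coef = np.zeros(X.shape[1])
        coef[active] = beta_a
        self.coef_ = coef
        return self

    def _newton(self, X, is_treated, weights, starts, ends, ridge):
        p = X.shape[1]
        beta = np.zeros(p)
        path = []
        converged = False
        ll, grad, hess = self._penalized(beta, X, is_treated, weights, starts, ends, ridge)
        for _ in range(self.max_iter):
            path.append(ll)
            if np.max(np.abs(grad), initial=0.0) < self.tol:
                converged = True
                break
            try:
                step = np.linalg.solve(-hess + 1e-10 * np.eye(p), grad)
            except np.linalg.LinAlgError:
                break
            # step-halving keeps the log-likelihood monotone (up to float
            # noise relative to its magnitude)
            ll_floor = ll - 1e-10 * (1.0 + abs(ll))
            for _half in range(40):
                cand = beta + step
                ll_new, g_new, h_new = self._penalized(
                    cand, X, is_treated, weights, starts, ends, ridge
                )
                if np.isfinite(ll_new) and ll_new >= ll_floor:
                    break
                step = step / 2.0
            else:
                break
            beta, ll, grad, hess = cand, ll_new, g_new, h_new
        else:
            converged = np.max(np.abs(grad), initial=0.0) < self.tol
        if np.max(np.abs(beta), initial=0.0) > 15:
            converged = False  # coefficients diverging: separation
        return beta, converged, ll, path

    @staticmethod
    def _penalized(beta, X, is_treated, weights, starts, ends, ridge):
        ll, grad, hess = _loglik_parts(beta, X, is_treated, weights, starts, ends)
        if ridge > 0:
            ll -= 0.5 * ridge * float(beta @ beta)
            grad = grad - ridge * beta
            hess = hess - ridge * np.eye(beta.size)
        return ll, grad, hess

    def predict_score(self, X) -> np.ndarray:
        """TCPS = logistic(x . beta); saturates stably for extreme eta."""
        return expit(np.asarray(X, float) @ self.coef_)


def conditional_loglik(beta, X, set_ids, is_treated, weights) -> float:
    """Weighted conditional log-likelihood at ``beta`` (sets with no
    comparator rows contribute zero)."""
    beta = np.asarray(beta, float)
    X, set_ids, is_treated, weights, starts, ends = _prepare(
        X, set_ids, is_treated, weights
    )
    if starts.size == 0:
        return 0.0
    ll, _, _ = _loglik_parts(beta, X, is_treated, weights, starts, ends, order=0)
    return ll


def conditional_loglik_grad(beta, X, set_ids, is_treated, weights) -> np.ndarray:
    beta = np.asarray(beta, float)
    X, set_ids, is_treated, weights, starts, ends = _prepare(
        X, set_ids, is_treated, weights
    )
    if starts.size == 0:
        return np.zeros(beta.size)
    _, grad, _ = _loglik_parts(beta, X, is_treated, weights, starts, ends, order=1)
    return grad


def fit_tcps(
    X,
    set_ids,
    is_treated,
    weights,
    ridge: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ConditionalLogitTCPS:
    """Fit the weighted exposure-set-conditional logistic model."""
    return ConditionalLogitTCPS(ridge=ridge, tol=tol, max_iter=max_iter).fit(
        X, set_ids, is_treated, weights
    )


def predict_tcps(model: ConditionalLogitTCPS, X) -> np.ndarray:
    """Scores in (0, 1) for arbitrary members, monotone in ``x . beta``."""
    if not np.all(np.isfinite(model.coef_)):
        raise ValueError("model coefficients are not finite")
    return model.predict_score(X)


def score_all_members(
    model: ConditionalLogitTCPS,
    encoder: CovariateEncoder,
    sets: ExposureSets,
    patients: pd.DataFrame,
) -> pd.DataFrame:
    """Predict the TCPS for every treated user and every candidate.

    Returns the long table ``set_id, patient_id, is_treated,
    candidate_index_date, score`` covering all members of all sets
    (sampled or not), with covariates resolved from ``patients``.
    """
    treated = sets.treated[["set_id", "patient_id", "index_date", "calendar_year"]].copy()
    treated["is_treated"] = 1
    cand = sets.candidates.rename(
        columns={"candidate_patient_id": "patient_id", "candidate_index_date": "index_date"}
    )[["set_id", "patient_id", "index_date", "calendar_year"]].copy()
    cand["is_treated"] = 0
    members = pd.concat([treated, cand], ignore_index=True)
    # the score depends only on (patient, calendar year): score each unique
    # combination once and broadcast, so huge candidate tables stay cheap
    if members["patient_id"].dtype.kind in "iu":
        combo = (
            members["patient_id"].to_numpy(np.int64) * 100_000
            + members["calendar_year"].to_numpy(np.int64)
        )
        uniq_combo, inverse = np.unique(combo, return_inverse=True)
        uniq = pd.DataFrame(
            {
                "patient_id": uniq_combo // 100_000,
                "calendar_year": uniq_combo % 100_000,
            }
        )
        merged = uniq.merge(patients, on="patient_id", how="left")
        X, _ = encoder.transform(merged)
        members["score"] = predict_tcps(model, X)[inverse]
    else:
        merged = members.merge(patients, on="patient_id", how="left")
        X, _ = encoder.transform(merged)
        members["score"] = predict_tcps(model, X)
    return members.rename(columns={"index_date": "candidate_index_date"})
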