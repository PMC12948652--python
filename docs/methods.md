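# Methods

This note documents the modelling assumptions behind the package: what the
synthetic generator emulates, how each design stage is defined, the defaults
and why, and the numerical choices that matter.

## Synthetic EHR generator

`pnu.simulate.generate_population` produces the three analysis-facing tables
(patients, prescriptions, events) from a configuration with known ground
truth. The generative model:

* **Entry** — patients enter uniformly over the study window (default
  2000-01-01 to 2004-12-31). Registered history before entry is
  365 + Exponential(mean 1500) days; a small fraction (default 2%) get under
  a year of history so the washout-exclusion path is exercised.
* **Covariates** — defaults are age ~ Normal(67, 12²) years, male ~
  Bernoulli(0.35), a chronic-comorbidity flag ~ Bernoulli(0.35), on scales
  typical of an older osteoarthritis-like primary-care population.
  Continuous covariates enter every linear predictor standardized by their
  sampling mean/SD, so all coefficients are per-SD.
* **Drug choice at initiation** — study drug with probability
  `logit⁻¹( logit(uptake_year) + β_choice · x )`. The default uptake curve
  rises 0.10 → 0.45 over 2000–2004, emulating a newly introduced drug class
  gaining market share.
* **Switching** — comparator initiators carry an exponential switch clock
  with log-rate `intercept + β_switch · x` (default intercept log 6e-4 per
  day, ≈ 20% switching within two years); the first scheduled refill at or
  after the latent switch time is issued as a study-drug prescription. A
  switch that would fall after non-persistence, death/transfer, the window
  end or the outcome never materializes.
* **Prescriptions** — fixed 28-day supplies; refill gaps Exponential(mean
  7 days) rounded to whole days; a per-refill stop probability of 0.06
  (median ≈ 11 issues per episode of care). No prescription is issued after
  the outcome, death or transfer.
* **Outcome** — exponential proportional hazards with linear predictor
  `θ·treated(t) + β_conf · x`, where `treated(t)` is time-fixed from the
  study-drug index date. θ = `true_log_hr` is the estimand's ground truth.
  Baseline rate 2.5e-4 per person-day (≈ 9% per person-year): a generic
  adverse-event scale chosen so desk-scale cohorts yield enough events for
  stable Cox estimates.
* **Censoring** — independent exponential death (4e-5/day), transfer
  (8e-5/day) and cirrhosis-analogue (5e-6/day) processes.

The truth record (latent switch/outcome times, true effect) is emitted
separately (`truth.json`) and is never read by the pipeline.

**What the generator does *not* emulate** — and hence what passing tests do
not establish about real data: informative censoring (switching and
discontinuation are covariate-driven but conditionally independent of the
outcome given x), time-varying covariates and hazards, measurement error and
coding artefacts, clustering by practice, unmeasured confounding, and
seasonality. Tests demonstrate that the *design machinery* is correct under
its own assumptions, not that those assumptions hold in any particular EHR.

`generate_confounded_scenario(strength, seed)` is the fixture for balance
and calibration studies: age and comorbidity drive drug choice
(β = 0.5·s, 0.7·s), switching (0.3·s, 0.5·s) and the outcome (0.5·s, 0.7·s),
with a null treatment effect. Its uptake curve is deliberately lower
(0.04 → 0.16) than the package default: with a minority-share study drug
every treated user faces a comparator pool several times their number, the
overlap regime that 1:1 without-replacement ATT matching presumes. At
strength 1 the unmatched standardized differences for the driving covariates
are ≈ 0.3–0.45.

## Base cohort

Entry is the first prescription of either class inside the window, subject
to (i) no prescription of either class within the washout (default 365 days)
before it and (ii) at least the washout length of registered history.
Study-drug entrants are incident new users; comparator entrants who later
receive the study drug in-window gain a prevalent new-user membership at
that date, keeping their comparator membership for pre-switch person-time.
Prior-prescription counts are counted from cohort entry onward, strictly
before the index date (the index prescription is the (k+1)-th); incident
users therefore have k = 0 by construction.

Treatment episodes follow `first issue + supply + successive overlapping
supplies + 30-day grace`. "Overlapping" bridges refill gaps of up to the
grace period by default (`bridge_gaps=True`), consistent with censoring at
discontinuation after a 30-day gap; strict supply-overlap is available as a
config switch. Dates are whole days; episode intervals are half-open
`[start, episode_end)`.

## Exposure sets

One set per study-drug user (`set_id` = treated patient id). Candidates are
the comparator members' prescriptions from their own entry up to (excluding)
any switch, each carrying its own prior count, days-since-entry and calendar
year. The caliper is inclusive (±30 days reads as a closed interval);
calendar year is compared on index dates. A comparator patient may appear in
many sets and contribute several candidate prescriptions — uniqueness is
enforced at matching. Empty sets are retained with a flag so the match-rate
diagnostic keeps its denominator. Time-since-entry for prevalent treated
users is measured from their own base-cohort entry, symmetrically with the
comparators.

## TCPS

Within-set sampling uses a per-set fraction `f = min(1, target/size)`
(default target 50), weight `w = 1/f`, treated row always kept with weight 1;
a single-global-fraction mode is also provided. Weights enter the
conditional likelihood only in the denominator sum over comparators — a
weighted pseudo-likelihood, isolated in `conditional_loglik` so an
alternative placement can be swapped in one place.

The fit is a damped Newton iteration on the exact gradient and Hessian,
gradient tolerance 1e-8, at most 100 iterations, with step-halving keeping
the log-likelihood monotone (up to float noise relative to its magnitude).
Columns constant within every set — calendar year under the hybrid
definition, for instance — carry no conditional information; their
coefficients are detected via the Hessian diagonal at β = 0 and pinned to
zero instead of drifting along flat directions. Divergence (|β| > 15) or
non-convergence at ridge 0 is flagged as separation and refitted with ridge
1e-6, logged, with `converged_ = False` retained.

Design encoding: continuous covariates standardized with fit-time mean/SD,
binary as 0/1, categorical one-hot against the first level with an explicit
"missing" level, calendar year (from each row's index date) categorical.
Prediction is `logit⁻¹(xᵀβ)` for every member of every set, computed once
per unique (patient, calendar-year) combination. Each exposure-set
definition gets its own fit, since the stacked data differ.

## Positivity and matching

Positivity is a one-time pre-matching check per set over *all* members:
kept iff the treated score lies inside the inclusive [min, max] of the
candidates' scores. Matching processes treated users in ascending index-date
order (ties by patient id); within a set the available candidate minimizing
|score difference| wins, exact ties resolved by earlier candidate index
date then smaller patient id. Without-replacement operates at the
comparator-person level: a matched person's every candidate prescription
becomes unavailable in all remaining sets. No caliper is applied to the
match distance. Unmatched treated users are logged with a reason
(`dropped_positivity`, `empty_set`, `exhausted_candidates`).

## Follow-up and estimation

Follow-up runs from the index date to the earliest of outcome, study end
(default: the window end), death, cirrhosis, transfer, or discontinuation
(end of the episode containing the index; a comparator is additionally
discontinued at any later switch to the study drug). Ties between causes
resolve in that precedence order; a same-day event yields a half-day
interval so all records have positive follow-up.

Hazard ratios come from an unstratified Cox model on the treatment
indicator with robust sandwich SEs (lifelines; Efron tie handling, matching
standard R practice), individual-level by default with a pair-clustered
option. Subgroup estimates (incident / prevalent) refit on the subgroup's
records. Zero events in an arm yields a flagged non-finite estimate rather
than an error. 95% CIs are `exp(β ± 1.96·se)`; the confidence-limit ratio is
their upper/lower ratio.

Balance: continuous ASD `|m₁−m₂| / √((s₁²+s₂²)/2)`; binary from pooled
proportion variance; multi-level categorical via the Mahalanobis-type
generalization over L−1 level indicators with a pseudo-inverse for
degenerate pooled covariance. The reported ASD compares the two matched
arms; the descriptive unmatched comparator group samples one candidate
prescription uniformly per nonempty set.

## Pipeline

`run_all` executes every requested (definition, caliper) configuration —
the prescription-based definition ignores the caliper list, with a logged
notice — each with deterministic stage seeds split from the master seed.
A failing configuration is recorded and the others proceed. The report
schema is identical across configurations so definitions are directly
comparable.

## Problem sizes in the test suite

Monte-Carlo tests use sizes chosen to keep the default run practical on one
CPU: null calibration runs 200 replicates at n = 2000; effect recovery
pools 20 replicates at n = 10 000 (tolerance is 3 Monte-Carlo SEs, which
scales with the size); balance restoration uses a single n = 10 000 run;
matching invariants replay 500 randomized instances, and the exposure-set
identities are checked on 15 simulated mini-cohorts.

## Known limitations

* The weighted pseudo-likelihood's weight placement is a modelling choice;
  alternatives (e.g. weighting the treated contribution) are not implemented.
* Positivity is checked once before matching; a set can pass and still lose
  its extreme candidates to earlier matches.
* 1:n and optimal (non-greedy) matching, match-distance calipers,
  high-dimensional propensity scores, SMR weighting, disease-risk scores and
  censoring weights are out of scope.
* The generator's outcome model keeps treatment time-fixed from index, so
  as-treated censoring is non-informative by construction.
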