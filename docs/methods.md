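# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `playtrace`. It is the package's own account of its
science; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Telemetry model and sequence encoding

A telemetry record is one click/game event: child, session (day 1 or 2),
level, timestamp, and a free-text status. Timestamps are a 24-hour clock
with millisecond resolution (`HH-MM-SS-mmm`) combined with a `month/day`
date column, so ordering survives midnight; ISO-8601 input is accepted as a
config option. Sorting is by (child, session, timestamp) with the input
file order as a stable tie-break — the log's own order is treated as
authoritative for simultaneous events.

Seven in-level statuses map to the symbol alphabet `{S,1,2,3,4,5,E}` after
whitespace/case normalization. How nutrition-fact reads appear in raw
telemetry is not documented upstream; this package reconstructs them as a
dedicated `fact_read` status carrying a `food_id`, which must be covered by
a user-supplied food taxonomy (good/bad). Unrecognized statuses are never
silently dropped: they either raise or are collected into a rejects report.

Episode segmentation opens at `S` and closes at the matching `E`. A new
start before the previous end closes the open episode as *incomplete*
(e.g. the session clock ran out mid-level); an end or avatar action outside
its episode's level is a structural error. Incomplete plays are retained
for chain estimation and measures, flagged — the data give no reason to
discard them, and dropping them would bias sequence lengths downward.
A *transition* is an adjacent symbol pair whose two symbols differ;
self-pairs (e.g. repeated shots `3→3`) are not transitions. Pattern
analyses use only the first encounter of each (child, level), identified
chronologically across both sessions.

## Markov chain

Pooled play is a discrete, time-homogeneous, first-order chain on the 7
states. Estimation is by raw MLE proportions of adjacent pairs, self-pairs
included. Numerical conventions:

* `E` is absorbing with an all-zero outgoing row (a level ends there);
  nothing enters `S`.
* No smoothing: a state never observed to be left has an *undefined*
  probability row (reported as such), not a uniform one.
* Simulation draws each next symbol from the current row and stops at `E`
  or a length cap (default 250 symbols); hitting the cap or an undefined
  row yields a truncated, E-less sequence, mirroring a play cut off
  mid-level.

## Gameplay measures

Per child, over first-encounter plays: `Level_max` (max level), `Avg_Seqlen`
(mean sequence length, counting both `S` and `E`), `Avg_transition` (mean
transitions per level), `AvgGFact`/`AvgBFact` (total good/bad fact reads
divided by *levels played*, not levels with any read), and the shield-kill
proportion

    Sum2_Sum2+4 = (Σ2 + α) / (Σ2 + Σ4 + 2α),    α = 0.5 by default.

The symmetric additive smoothing keeps the proportion strictly inside
(0, 1) for children with no kills of one kind; α is configurable because
the exact smoothing used originally is not recoverable from the published
description (with α = 0.5 a child with 0 shield kills against 165 shot
kills scores 0.003, matching the order of magnitude of reported minima).
Cohort summaries report min/mean/max, *sample* variance (n−1), and
CV = 100·sd/mean; sample variance is the convention consistent with the
published summary table's internal mean/variance/CV arithmetic.

## Outcome statistics

* **Mann-Whitney U** (min-rank-sum convention, two-sided). The exact branch
  enumerates the permutation null with a dynamic program over doubled
  midranks — exact and tie-safe at study scale (used automatically when
  min(n) ≤ 10 and n ≤ 25); the two-sided p is P(U_min ≤ observed). The
  asymptotic branch is scipy's tie-corrected normal approximation with
  continuity correction. Two identical pooled samples are degenerate and
  return p = 1 with a flag.
* **Cohen's d** uses the Bessel-corrected pooled SD. One published change-
  score SD is printed with a stray negative sign; SDs being nonnegative,
  the magnitude is used.
* **Power** is the noncentral-t power of the two-sample t test
  (ncp = d·√(n₁n₂/(n₁+n₂))); sample-size planning walks the smallest even
  total n meeting the target. The default is one-sided, the only sidedness
  that reproduces the trial's published planning figure of 102 at d = 0.50,
  α = .05, power = .80 (two-sided gives 128); the flag is exposed.
* **Cohen's kappa** is computed from marginal products; two constant,
  identical raters (p_e = 1) are defined as κ = 1.

## Association analysis

Kendall tau-b (tie-adjusted) screens each measure against GoodChoice,
exact-enumeration p for n ≤ 8 without ties, asymptotic otherwise. The
outcome family is chosen by AIC between a normal fit (k = 2, MLE sd) and a
Poisson fit (k = 1, rate = mean); zero-variance outcomes make the normal
likelihood unbounded and are flagged. Stepwise selection is bidirectional
AIC minimization starting from the full model, deterministic given column
order, ties broken toward the smaller model; forced adjustment terms
(GoodBase) are never subject to selection; collinear candidates are dropped
with a warning. Final models are OLS with HC1 standard errors and log-link
Poisson ML with the classical HC0 sandwich — the robust-SE flavors are
configurable and recorded in output metadata, since the original analysis
specifies only "robust SE". Shapiro-Wilk checks residual normality.

## Synthetic cohorts

The generator emulates the study conditions: 104 children, two equal arms
across 3 schools, two sessions one week apart, levels played ~ 1 +
Poisson(14) (mean 15, range ≈ 2–23, capped at the game's 80), roughly one
sequence in seven a replay, and per-level fact reads ~ Poisson(0.43 good,
0.12 bad). Each treatment child's transition rows are drawn
Dirichlet(κ·base row) around a base chain (κ = 60 by default; κ = ∞ gives
homogeneous players). The base chain is anchored to the three published
pooled probabilities (P(3→3) = .67, P(3→4) = .19, P(1→2) = .08) with the
remaining mass spread plausibly (shooting as the hub state, small exit
rates so sequences average ~60–70 symbols); it is illustrative, not ground
truth. Control children have outcomes but no telemetry, as in a board-game
control arm.

Outcomes follow a binomial-logit model per day: healthy choices ~
Binomial(2, p) with logit p = β₀ + β_g·AvgGFact + β_b·AvgBFact +
β_base·GoodBase for the treatment arm and β₀ + β_base·GoodBase for
controls. Defaults β₀ = −1.35, β_g = 4, β_b = −4, β_base = 0.9,
P(GoodBase) = 0.38, 5% missing GoodBase: these give arm means near the
reported 2.48 vs 1.10 and sign-match the reported regression table. The
covariates entering the logit are the child's *realized* first-encounter
fact-reading averages, computed exactly as the pipeline later measures them
(including reads from a same-session replay of a first-encounter level,
which share the (session, level) key) — so parameter recovery is exact in
expectation rather than attenuated by covariate mismatch. The binomial
rather than normal/Poisson form respects the hard 0–2 per-day range while
remaining sign-compatible; the analysis stage still fits the normal and
Poisson models to it, as the original analysis did to its bounded count.

`recover_parameters` reruns the full pipeline (events → sequences → first
encounters → measures) and refits the *generating* family — a binomial GLM
with logit link, 4 trials per child, HC0 robust SEs — on treatment children
with complete outcomes and known GoodBase, reporting estimates, robust CIs
and coverage against the true β. The analysis-side normal/Poisson fits
estimate coefficients on a different scale and are therefore checked for
sign, not value.

What the generator does **not** emulate: within-child learning across
levels (rows are time-homogeneous), level-difficulty gradients, session
fatigue, the exact empirical distributions of the unpublished raw data, and
any dependence of fact reading on play style. Passing recovery tests
therefore show the pipeline is statistically faithful to its own model
class, not that the original study's numbers are reproduced.

## Problem sizes and statistical checks

Chosen problem sizes: Markov recovery uses 2000 simulated sequences at a
0.02/cell tolerance, run against a chain with balanced state occupancy so
the tolerance exceeds 3 sampling SEs for every cell (under the default base
chain the rarely visited shield-kill state makes 0.02 barely more than one
SE — a check of noise, not of the estimator). Coefficient recovery uses one
1000-child cohort (3-robust-SE check) plus 200 default-size cohorts for CI
coverage; at ~50 analyzable treatment children per cohort the sandwich CIs
show the usual mild small-sample undercoverage (≈92–95% observed against
the nominal 95%). Exact-test implementations are compared against
brute-force enumeration oracles (all group labelings for Mann-Whitney;
O(n²) pair counting for tau-b).

## Pipeline conventions

Site exclusions are asymmetric by design: play-pattern outputs (sequences,
chain, measures) use all sites, while outcome analyses honor the exclusion
list — matching a trial in which one school's food choices were potentially
contaminated but its telemetry remained valid. Children lacking either
day's outcome are excluded from outcome analyses only. The manifest records
row counts at every filter (CONSORT-style: children in = analyzed +
excluded, with reasons), the options used, and the package version; reruns
on identical inputs are byte-identical.

## Known limitations

* The exact Mann-Whitney DP is O(n₁ · (Σ2r)) per call — fine to n ≈ 25,
  not meant for large samples (the asymptotic branch takes over).
* Stepwise-AIC selection inherits the usual caveats (greedy, inflated
  in-sample fit); it is provided because the original analysis used it,
  with the exhaustive-search agreement checked only at small candidate
  counts.
* GoodID outcomes are generated with a group-level effect only (no
  dependence on play measures); the association stage analyzes GoodChoice,
  as in the original objective.
* The fact-read telemetry schema is a reconstruction; real exports from the
  game backend would need a mapping step onto the CSV/JSONL contract.
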