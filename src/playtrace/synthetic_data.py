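"""Synthetic cohorts with the statistical structure the analysis assumes.

The study's raw data are not deposited, so every pipeline stage is exercised
on simulated cohorts: a two-arm trial in which treatment children produce
telemetry (per-level play sequences from child-specific Markov chains drawn
around a common base chain, plus post-level nutrition-fact reads) and both
arms produce food-choice outcomes whose dependence on fact reading follows a
binomial-logit model per day.  The generator records its own parameters so a
full pipeline run can be checked against ground truth
(:func:`recover_parameters`).

Default parameters emulate the study conditions: 104 children in two equal
arms across 3 schools, two sessions a week apart, ~15 levels played on
average (range ~2-23), roughly one sequence in seven being a replay, mean
fact-read rates of 0.43 good and 0.12 bad facts per level, and outcome
coefficients whose signs match the reported associations (good facts up, bad
facts down, healthy baseline preference up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from . import association
from .markov_model import STATES, TransitionMatrix, estimate_transition_matrix, simulate_sequence
from .play_measures import compute_cohort_measures
from .sequence_builder import (
    build_level_sequences,
    filter_first_encounters,
    status_for_symbol,
)
from .telemetry_io import (
    STATUS_FACT_READ,
    ChildRecord,
    FoodTaxonomy,
    GameEvent,
    load_food_taxonomy,
)

__all__ = [
    "DEFAULT_TAXONOMY",
    "SyntheticConfig",
    "SyntheticCohort",
    "RecoveryReport",
    "default_base_matrix",
    "generate_cohort",
    "recover_parameters",
]

#: The study's three food pairs (drink / savory / sweet), healthy vs not.
DEFAULT_TAXONOMY = {
    "water": "good", "nimbooz": "bad",
    "cashews": "good", "chips": "bad",
    "raisins": "good", "chocolate": "bad",
}

_SESSION_DATES = {1: datetime(2019, 7, 10, 9, 0), 2: datetime(2019, 7, 17, 9, 0)}


def default_base_matrix() -> np.ndarray:
    """Illustrative base chain anchored to the reported level-1 probabilities.

    The three transition probabilities printed for the pooled level-1 chain
    (3->3 = .67, 3->4 = .19, 1->2 = .08) are fixed; the remaining mass is
    spread over plausible moves (bad-food shooting as the hub state, small
    exit probabilities so sequences run tens of events).  Illustrative, not
    ground truth.
    """
    p = np.zeros((7, 7))
    rows = {
        #      S     1     2      3     4      5      E
        "S": [0.00, 0.16, 0.00, 0.720, 0.00, 0.120, 0.000],
        "1": [0.00, 0.14, 0.08, 0.640, 0.00, 0.120, 0.020],
        "2": [0.00, 0.15, 0.30, 0.470, 0.00, 0.060, 0.020],
        "3": [0.00, 0.05, 0.00, 0.670, 0.19, 0.075, 0.015],
        "4": [0.00, 0.14, 0.00, 0.600, 0.10, 0.140, 0.020],
        "5": [0.00, 0.16, 0.00, 0.600, 0.00, 0.210, 0.030],
        "E": [0.00, 0.00, 0.00, 0.000, 0.00, 0.000, 0.000],
    }
    for i, s in enumerate(STATES):
        p[i] = rows[s]
    return p


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the defaults are the emulated study conditions."""

    n_children: int = 104
    p_treatment: float = 0.5
    base_matrix: Optional[np.ndarray] = None      # None -> default_base_matrix()
    dirichlet_concentration: float = 60.0         # per-child heterogeneity kappa
    levels_lambda: float = 14.0                   # levels played ~ 1 + Poisson
    max_levels: int = 80
    max_seq_len: int = 250
    replay_rate: float = 0.16                     # per-level chance of one replay
    fact_rate_good: float = 0.43                  # fact reads per level ~ Poisson
    fact_rate_bad: float = 0.12
    beta0: float = -1.35                          # per-day choice logit model
    beta_gfact: float = 4.0
    beta_bfact: float = -4.0
    beta_base: float = 0.9
    p_goodbase: float = 0.38
    missing_goodbase_rate: float = 0.05
    id_logit_control: float = 1.88                # per-day identification model
    id_logit_treat: float = 0.47
    schools: tuple[str, ...] = ("A", "B", "C")
    seed: int = 0

    def resolved_base_matrix(self) -> np.ndarray:
        m = self.base_matrix if self.base_matrix is not None else default_base_matrix()
        return np.asarray(m, dtype=float)

    def validate(self) -> None:
        m = self.resolved_base_matrix()
        TransitionMatrix.from_probs(m)  # raises on an invalid base matrix
        if not np.isclose(m[0].sum(), 1.0):
            raise ValueError("the base matrix S row must be a distribution")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if not 0 <= self.p_goodbase <= 1:
            raise ValueError("p_goodbase must lie in [0, 1]")
        if self.fact_rate_good < 0 or self.fact_rate_bad < 0:
            raise ValueError("fact rates must be nonnegative")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated telemetry, outcome records, and the generating truth."""

    events: list[GameEvent]
    children: list[ChildRecord]
    truth: SyntheticConfig


def _child_matrix(base: np.ndarray, kappa: float, rng: np.random.Generator) -> TransitionMatrix:
    """Per-child transition rows drawn Dirichlet(kappa * base row) on the support."""
    p = np.zeros_like(base)
    for i in range(6):  # all rows but absorbing E
        support = base[i] > 0
        if not support.any():
            continue
        if math.isinf(kappa):
            p[i] = base[i]
        else:
            p[i, support] = rng.dirichlet(kappa * base[i, support])
    return TransitionMatrix.from_probs(p)


def _play_schedule(n_levels: int, replay_rate: float, rng: np.random.Generator) -> list[int]:
    """Ordered list of levels played: 1..n in order, with occasional replays."""
    schedule: list[int] = []
    for level in range(1, n_levels + 1):
        schedule.append(level)
        if level > 1 and rng.random() < replay_rate:
            schedule.append(int(rng.integers(1, level + 1)))  # replay some earlier level
    return schedule


def _emit_play(child_id: str, session: int, level: int, symbols: str,
               clock_ms: int, rng: np.random.Generator,
               cfg: SyntheticConfig, taxonomy: FoodTaxonomy,
               events: list[GameEvent]) -> int:
    """Materialize one play (and its fact reads, if completed) as events."""
    for sym in symbols:
        clock_ms += int(rng.exponential(1200)) + 1  # ~1.2 s between actions
        events.append(GameEvent(
            child_id=child_id, session=session, level=level,
            timestamp=_SESSION_DATES[session] + timedelta(milliseconds=clock_ms),
            status=status_for_symbol(sym),
            event_class={"S": "level_start", "E": "level_end"}.get(sym, "avatar_action"),
        ))
    if symbols.endswith("E"):  # nutrition facts live on the post-level summary screen
        n_good = rng.poisson(cfg.fact_rate_good)
        n_bad = rng.poisson(cfg.fact_rate_bad)
        foods = ([taxonomy.good_foods[int(i)] for i in
                  rng.integers(0, len(taxonomy.good_foods), n_good)] +
                 [taxonomy.bad_foods[int(i)] for i in
                  rng.integers(0, len(taxonomy.bad_foods), n_bad)])
        for food in foods:
            clock_ms += int(rng.exponential(2000)) + 1
            events.append(GameEvent(
                child_id=child_id, session=session, level=level,
                timestamp=_SESSION_DATES[session] + timedelta(milliseconds=clock_ms),
                status=STATUS_FACT_READ, event_class="fact_read", food_id=food,
            ))
    return clock_ms


def generate_cohort(config: SyntheticConfig = SyntheticConfig()) -> SyntheticCohort:
    """Generate a full synthetic cohort, reproducible from ``config.seed``.

    Treatment children produce telemetry over two sessions (the second
    resuming where the first stopped); control children played a board game
    and so have outcome records only.  Per-day healthy choices are
    Binomial(2, p) with logit p = beta0 + beta_gfact*AvgGFact +
    beta_bfact*AvgBFact + beta_base*GoodBase for the treatment arm and
    beta0 + beta_base*GoodBase for controls, where AvgGFact/AvgBFact are the
    child's realized first-encounter fact-reading averages — exactly the
    covariates the analysis pipeline later measures.
    """
    config.validate()
    base = config.resolved_base_matrix()
    taxonomy = load_food_taxonomy(DEFAULT_TAXONOMY)
    width = max(3, len(str(config.n_children)))
    child_seeds = np.random.SeedSequence(config.seed).spawn(config.n_children)

    events: list[GameEvent] = []
    children: list[ChildRecord] = []
    for i, seed in enumerate(child_seeds):
        rng = np.random.default_rng(seed)
        child_id = f"C{i + 1:0{width}d}"
        school = config.schools[int(rng.integers(0, len(config.schools)))]
        treated = rng.random() < config.p_treatment
        gender = "M" if rng.random() < 0.5 else "F"
        bmi = None if school == "C" else round(float(rng.normal(18.3, 4.0)), 1)

        avg_g = avg_b = 0.0
        if treated:
            tm = _child_matrix(base, config.dirichlet_concentration, rng)
            n_levels = min(1 + int(rng.poisson(config.levels_lambda)), config.max_levels)
            schedule = _play_schedule(n_levels, config.replay_rate, rng)
            half = (len(schedule) + 1) // 2
            clock = {1: 0, 2: 0}
            fact_counts: dict[tuple[int, int], tuple[int, int]] = {}
            seen: set[tuple[int, int]] = set()
            first_keys: set[tuple[int, int]] = set()
            pre = len(events)
            for j, level in enumerate(schedule):
                session = 1 if j < half else 2
                symbols = simulate_sequence(tm, max_len=config.max_seq_len, rng=rng)
                if level not in {lv for (_, lv) in seen}:
                    first_keys.add((session, level))
                seen.add((session, level))
                clock[session] = _emit_play(child_id, session, level, symbols,
                                            clock[session], rng, config, taxonomy, events)
            # realized first-encounter fact averages (the outcome covariates)
            n_first = len({lv for (_, lv) in first_keys})
            good = bad = 0
            for ev in events[pre:]:
                if ev.event_class == "fact_read" and (ev.session, ev.level) in first_keys:
                    if taxonomy.classify(ev.food_id) == "good":
                        good += 1
                    else:
                        bad += 1
            avg_g, avg_b = good / n_first, bad / n_first

        good_base = int(rng.random() < config.p_goodbase)
        logit = config.beta0 + config.beta_base * good_base
        if treated:
            logit += config.beta_gfact * avg_g + config.beta_bfact * avg_b
        p_choice = float(expit(logit))
        p_id = float(expit(config.id_logit_control + config.id_logit_treat * treated))
        gb_missing = rng.random() < config.missing_goodbase_rate
        children.append(ChildRecord(
            child_id=child_id,
            group="treatment" if treated else "control",
            school=school,
            good_choice_day1=int(rng.binomial(2, p_choice)),
            good_choice_day2=int(rng.binomial(2, p_choice)),
            good_id_day1=int(rng.binomial(4, p_id)),
            good_id_day2=int(rng.binomial(4, p_id)),
            good_base=None if gb_missing else good_base,
            gender=gender, bmi=bmi,
        ))

    events.sort(key=lambda e: (e.child_id, e.session, e.timestamp))
    return SyntheticCohort(events=events, children=children, truth=config)


# --------------------------------------------------------------------------
# Parameter recovery
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryReport:
    """Estimated vs true outcome-model coefficients after a full pipeline run."""

    params: pd.DataFrame      # term, truth, estimate, robust_se, ci_low, ci_high, covered
    n_children: int
    n_plays: int
    markov_max_abs_error: float

    @property
    def all_covered(self) -> bool:
        return bool(self.params["covered"].all())

    @property
    def max_se_distance(self) -> float:
        return float((abs(self.params["estimate"] - self.params["truth"])
                      / self.params["robust_se"]).max())


def recover_parameters(cohort: SyntheticCohort, alpha: float = 0.5,
                       ci_level: float = 0.95) -> RecoveryReport:
    """Run the full pipeline on a synthetic cohort and compare against truth.

    Sequences are rebuilt from the raw events, filtered to first encounters,
    summarized into per-child measures, and the generating binomial-logit
    outcome model is refit (GLM, logit link, 4 trials per child, sandwich
    robust SEs) on treatment children with complete outcomes and a known
    baseline preference.  Also reports the max absolute cell error of the
    pooled Markov estimate against the base chain.
    """
    cfg = cohort.truth
    stage = "sequence building"
    try:
        plays = build_level_sequences(cohort.events)
        first = filter_first_encounters(plays)
        stage = "markov estimation"
        tm = estimate_transition_matrix(first)
        markov_err = float(np.max(np.abs(tm.probs - cfg.resolved_base_matrix())))
        stage = "measure computation"
        taxonomy = load_food_taxonomy(DEFAULT_TAXONOMY)
        fact_events = [e for e in cohort.events if e.event_class == "fact_read"]
        measures = compute_cohort_measures(first, fact_events, taxonomy, alpha=alpha)
        stage = "outcome regression"
        outcome = pd.DataFrame([
            {"child_id": c.child_id, "GoodChoice": c.good_choice,
             "good_base": c.good_base}
            for c in cohort.children if c.group == "treatment"
        ])
        data = measures.merge(outcome, on="child_id", how="inner")
        data = data.dropna(subset=["GoodChoice", "good_base"])
        import statsmodels.api as sm
        endog = np.column_stack([data["GoodChoice"], 4 - data["GoodChoice"]])
        exog = pd.DataFrame({
            association.INTERCEPT: np.ones(len(data)),
            "AvgGFact": data["AvgGFact"].to_numpy(float),
            "AvgBFact": data["AvgBFact"].to_numpy(float),
            "GoodBase": data["good_base"].to_numpy(float),
        })
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(cov_type="HC0")
    except Exception as exc:
        raise RuntimeError(f"parameter recovery failed at stage: {stage}") from exc

    truth = {"Intercept": cfg.beta0, "AvgGFact": cfg.beta_gfact,
             "AvgBFact": cfg.beta_bfact, "GoodBase": cfg.beta_base}
    ci = res.conf_int(alpha=1 - ci_level)
    rows = []
    for name, true_val in truth.items():
        lo, hi = float(ci.loc[name, 0]), float(ci.loc[name, 1])
        rows.append({"term": name, "truth": true_val,
                     "estimate": float(res.params[name]),
                     "robust_se": float(res.bse[name]),
                     "ci_low": lo, "ci_high": hi,
                     "covered": lo <= true_val <= hi})
    return RecoveryReport(params=pd.DataFrame(rows), n_children=int(len(data)),
                          n_plays=len(first), markov_max_abs_error=markov_err)
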