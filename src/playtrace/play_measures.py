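"""Per-child MDA gameplay measures and their cohort summary.

Six measures summarize how a child played, organized by the
mechanics-dynamics-aesthetics (MDA) decomposition adapted to telemetry
(aesthetics being unobservable from logs):

* mechanics — ``Level_max`` (highest level played over both sessions) and
  ``Avg_Seqlen`` (mean encoded-sequence length across levels played);
* dynamics — ``Avg_transition`` (mean number of state-changing adjacent
  pairs per level);
* strategies — ``Sum2_Sum2+4``, the proportion of robot kills achieved via
  the highly rewarded good-food shield (state 2) out of all kills (states 2
  and 4), smoothed into the open interval (0, 1);
* food learning — ``AvgGFact`` and ``AvgBFact``, mean good/bad nutrition
  facts read per level played.

All measures are computed on first-encounter plays only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .sequence_builder import LevelPlay
from .telemetry_io import FoodTaxonomy, GameEvent, TaxonomyError

__all__ = [
    "MEASURE_NAMES",
    "PlayMeasures",
    "shield_kill_proportion",
    "coefficient_of_variation",
    "compute_child_measures",
    "compute_cohort_measures",
    "summarize_measures",
]

#: Canonical measure names, in report order.
MEASURE_NAMES = ("Level_max", "Avg_Seqlen", "Avg_transition",
                 "Sum2_Sum2+4", "AvgGFact", "AvgBFact")


@dataclass(frozen=True)
class PlayMeasures:
    """The six-measure gameplay profile of one child."""

    child_id: str
    level_max: int
    avg_seqlen: float
    avg_transition: float
    shield_prop: float
    avg_gfact: float
    avg_bfact: float
    n_levels: int

    def as_dict(self) -> dict:
        return {"child_id": self.child_id, "Level_max": self.level_max,
                "Avg_Seqlen": self.avg_seqlen, "Avg_transition": self.avg_transition,
                "Sum2_Sum2+4": self.shield_prop, "AvgGFact": self.avg_gfact,
                "AvgBFact": self.avg_bfact, "n_levels": self.n_levels}


def shield_kill_proportion(sum2: int, sum4: int, alpha: float = 0.5) -> float:
    """Smoothed proportion of kills by shield: (sum2 + a) / (sum2 + sum4 + 2a).

    The symmetric additive smoothing keeps the fraction legal — strictly
    inside (0, 1) — even for children with no kills of one kind (or none at
    all).  With ``alpha=0`` the raw proportion is returned and requires
    ``sum2 + sum4 > 0``.
    """
    if sum2 < 0 or sum4 < 0:
        raise ValueError("kill counts must be nonnegative")
    if alpha < 0:
        raise ValueError("smoothing alpha must be nonnegative")
    denom = sum2 + sum4 + 2.0 * alpha
    if denom == 0:
        raise ValueError("sum2 + sum4 = 0 with alpha = 0: proportion undefined")
    return (sum2 + alpha) / denom


def coefficient_of_variation(mean: float, variance: float) -> float:
    """CV in percent: 100 * sqrt(variance) / mean (0 for a constant measure)."""
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    if variance == 0:
        return 0.0
    if mean <= 0:
        raise ValueError("CV requires a positive mean for a nonconstant measure")
    return 100.0 * float(np.sqrt(variance)) / float(mean)


def _count_fact_reads(child_id: str, plays: Sequence[LevelPlay],
                      fact_events: Iterable[GameEvent],
                      taxonomy: Optional[FoodTaxonomy]) -> tuple[int, int]:
    """Good/bad fact-read totals for the (session, level) pairs of the plays."""
    keys = {(p.session, p.level) for p in plays}
    good = bad = 0
    for ev in fact_events:
        if ev.child_id != child_id or ev.event_class != "fact_read":
            continue
        if (ev.session, ev.level) not in keys:
            continue
        if taxonomy is None:
            raise TaxonomyError("fact-read events present but no taxonomy given")
        if taxonomy.classify(ev.food_id) == "good":
            good += 1
        else:
            bad += 1
    return good, bad


def compute_child_measures(plays: Sequence[LevelPlay],
                           fact_events: Iterable[GameEvent] = (),
                           taxonomy: Optional[FoodTaxonomy] = None,
                           alpha: float = 0.5) -> PlayMeasures:
    """Compute one child's six gameplay measures from first-encounter plays.

    ``fact_events`` are that child's fact-read telemetry records; only reads
    attached to a (session, level) present in ``plays`` count, and the
    AvgGFact/AvgBFact denominators are the number of levels played (not the
    number of levels with any read).
    """
    plays = list(plays)
    if not plays:
        raise ValueError("cannot compute measures for a child with zero plays")
    child_ids = {p.child_id for p in plays}
    if len(child_ids) != 1:
        raise ValueError(f"plays span several children: {sorted(child_ids)}")
    child_id = plays[0].child_id
    n_levels = len(plays)
    sum2 = sum(p.symbols.count("2") for p in plays)
    sum4 = sum(p.symbols.count("4") for p in plays)
    good, bad = _count_fact_reads(child_id, plays, fact_events, taxonomy)
    return PlayMeasures(
        child_id=child_id,
        level_max=max(p.level for p in plays),
        avg_seqlen=float(np.mean([p.length for p in plays])),
        avg_transition=float(np.mean([p.n_transitions for p in plays])),
        shield_prop=shield_kill_proportion(sum2, sum4, alpha=alpha),
        avg_gfact=good / n_levels,
        avg_bfact=bad / n_levels,
        n_levels=n_levels,
    )


def compute_cohort_measures(plays: Sequence[LevelPlay],
                            fact_events: Iterable[GameEvent] = (),
                            taxonomy: Optional[FoodTaxonomy] = None,
                            alpha: float = 0.5) -> pd.DataFrame:
    """Per-child measures for a whole cohort (one row per child)."""
    fact_events = list(fact_events)
    by_child: dict[str, list[LevelPlay]] = {}
    for p in plays:
        by_child.setdefault(p.child_id, []).append(p)
    rows = [compute_child_measures(ps, fact_events, taxonomy, alpha=alpha).as_dict()
            for ps in by_child.values()]
    return pd.DataFrame(rows, columns=["child_id", *MEASURE_NAMES, "n_levels"])


def summarize_measures(cohort: Union[pd.DataFrame, Sequence[PlayMeasures]]) -> pd.DataFrame:
    """Cohort summary per measure: Min, Mean, Max, Variance, CV (percent).

    Variance is the sample variance (n-1 denominator); CV = 100*sd/mean.
    Requires at least two children.
    """
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.DataFrame([m.as_dict() for m in cohort])
    if len(cohort) < 2:
        raise ValueError("cohort summary requires at least 2 children")
    rows = []
    for name in MEASURE_NAMES:
        x = cohort[name].to_numpy(dtype=float)
        mean = float(np.mean(x))
        var = float(np.var(x, ddof=1))
        rows.append({"measure": name, "Min": float(np.min(x)), "Mean": mean,
                     "Max": float(np.max(x)), "Variance": var,
                     "CV": coefficient_of_variation(mean, var)})
    return pd.DataFrame(rows).set_index("measure")
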