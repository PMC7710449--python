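"""Encoding telemetry into 7-symbol play sequences, one per level encounter.

Each play of a level is encoded over the alphabet ``{S,1,2,3,4,5,E}``: S/E
mark level start and finish, and 1-5 are the avatar events (good-food shield,
robot destroyed by shield, bad-food shot, robot destroyed by shot, avatar hit).
Events ordered chronologically within a level yield sequences such as
``S124331E`` — length 8 with 6 transitions, a transition being an adjacent
pair whose two symbols differ (3->3 is not a transition).

Pattern analysis uses only the *first encounter* of each level by each child;
replays are filtered out by :func:`filter_first_encounters`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional, Sequence

import pandas as pd

from .telemetry_io import (
    AVATAR_STATUSES,
    STATUS_LEVEL_END,
    STATUS_LEVEL_START,
    GameEvent,
    normalize_status,
)

__all__ = [
    "SYMBOLS",
    "LabelingError",
    "StructuralError",
    "LevelPlay",
    "label_event",
    "status_for_symbol",
    "count_transitions",
    "build_level_sequences",
    "filter_first_encounters",
    "plays_to_frame",
]


class LabelingError(ValueError):
    """An event description does not match any feature label."""


class StructuralError(ValueError):
    """The event stream violates level-episode structure."""


#: The 7-state alphabet in canonical order.
SYMBOLS = ("S", "1", "2", "3", "4", "5", "E")

_SYMBOL_BY_STATUS = {
    normalize_status(STATUS_LEVEL_START): "S",
    normalize_status(STATUS_LEVEL_END): "E",
    normalize_status(AVATAR_STATUSES[0]): "1",  # consumes good food -> shield
    normalize_status(AVATAR_STATUSES[1]): "2",  # robot killed by shield
    normalize_status(AVATAR_STATUSES[2]): "3",  # shoots bad food ammo
    normalize_status(AVATAR_STATUSES[3]): "4",  # robot killed by shots
    normalize_status(AVATAR_STATUSES[4]): "5",  # player hit by robot
}

_STATUS_BY_SYMBOL = {
    "S": STATUS_LEVEL_START,
    "E": STATUS_LEVEL_END,
    "1": AVATAR_STATUSES[0],
    "2": AVATAR_STATUSES[1],
    "3": AVATAR_STATUSES[2],
    "4": AVATAR_STATUSES[3],
    "5": AVATAR_STATUSES[4],
}


def label_event(status: str) -> str:
    """Map an event description to its feature label (symbol).

    Matching is exact after whitespace collapsing and case folding.
    """
    try:
        return _SYMBOL_BY_STATUS[normalize_status(status)]
    except KeyError:
        raise LabelingError(f"no feature label for status {status!r}") from None


def status_for_symbol(symbol: str) -> str:
    """Inverse of :func:`label_event`: canonical event description for a symbol."""
    try:
        return _STATUS_BY_SYMBOL[symbol]
    except KeyError:
        raise LabelingError(f"unknown symbol {symbol!r}") from None


def count_transitions(symbols: str) -> int:
    """Number of adjacent pairs whose symbols differ (state changes)."""
    if len(symbols) < 1:
        raise ValueError("sequence must have at least one symbol")
    return sum(a != b for a, b in zip(symbols, symbols[1:]))


@dataclass(frozen=True)
class LevelPlay:
    """One child's encoded symbol sequence for one encounter of one level."""

    child_id: str
    session: int
    level: int
    encounter_index: int
    symbols: str
    complete: bool
    start_time: Optional[datetime] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.symbols or self.symbols[0] != "S":
            raise ValueError(f"sequence must begin with S, got {self.symbols!r}")
        bad = set(self.symbols) - set(SYMBOLS)
        if bad:
            raise ValueError(f"sequence has symbols outside the alphabet: {sorted(bad)}")
        if self.complete:
            if not self.symbols.endswith("E") or self.symbols.count("E") != 1:
                raise ValueError("a complete sequence ends with exactly one E")
        elif "E" in self.symbols:
            raise ValueError("an incomplete sequence must not contain E")

    @property
    def length(self) -> int:
        return len(self.symbols)

    @property
    def n_transitions(self) -> int:
        return count_transitions(self.symbols)


def build_level_sequences(events: Iterable[GameEvent]) -> list[LevelPlay]:
    """Segment a chronologically sorted event stream into per-level sequences.

    Each episode opens at a ``level_start`` and closes at the matching
    ``level_end``; a new start before the previous end closes the open episode
    as *incomplete* (the session moved on mid-level, e.g. the app was closed).
    Fact-read events belong to the post-level summary screen and are excluded
    from the symbols.  A ``level_end`` or avatar action outside its episode's
    level raises :class:`StructuralError`.

    Returns plays in chronological order per child, with ``encounter_index``
    numbering repeats of the same (child, level) across both sessions.
    """
    plays: list[LevelPlay] = []

    def close(state: dict, complete: bool) -> None:
        plays.append(LevelPlay(
            child_id=state["child"], session=state["session"], level=state["level"],
            encounter_index=0, symbols="".join(state["symbols"]),
            complete=complete, start_time=state["start"],
        ))

    current: Optional[dict] = None
    current_key: Optional[tuple] = None
    for ev in events:
        key = (ev.child_id, ev.session)
        if current is not None and key != current_key:
            close(current, complete=False)
            current = None
        current_key = key
        if ev.event_class == "fact_read":
            continue
        if ev.event_class == "level_start":
            if current is not None:
                close(current, complete=False)
            current = {"child": ev.child_id, "session": ev.session, "level": ev.level,
                       "symbols": ["S"], "start": ev.timestamp}
            continue
        if current is None:
            raise StructuralError(
                f"{ev.status!r} for child {ev.child_id} session {ev.session} "
                f"level {ev.level} occurs outside any level episode")
        if ev.level != current["level"]:
            raise StructuralError(
                f"interleaved levels for child {ev.child_id} session {ev.session}: "
                f"event at level {ev.level} inside episode of level {current['level']}")
        if ev.event_class == "level_end":
            current["symbols"].append("E")
            close(current, complete=True)
            current = None
        else:
            current["symbols"].append(label_event(ev.status))
    if current is not None:
        close(current, complete=False)

    # number encounters of each (child, level) chronologically
    order: dict[tuple, int] = {}
    numbered = []
    for p in plays:
        k = (p.child_id, p.level)
        order[k] = order.get(k, 0) + 1
        numbered.append(LevelPlay(child_id=p.child_id, session=p.session, level=p.level,
                                  encounter_index=order[k], symbols=p.symbols,
                                  complete=p.complete, start_time=p.start_time))
    return numbered


def filter_first_encounters(plays: Sequence[LevelPlay]) -> list[LevelPlay]:
    """Keep only the chronologically earliest play of each (child, level).

    Replays of a level — in either session — are dropped, so the output has
    exactly one play per distinct (child, level) pair.  Idempotent.
    """
    best: dict[tuple, tuple] = {}
    for i, p in enumerate(plays):
        k = (p.child_id, p.level)
        rank = (p.encounter_index if p.encounter_index > 0 else 1,
                p.session, p.start_time or datetime.min, i)
        if k not in best or rank < best[k][0]:
            best[k] = (rank, i, p)
    kept = sorted(best.values(), key=lambda t: t[1])
    return [t[2] for t in kept]


def plays_to_frame(plays: Sequence[LevelPlay]) -> pd.DataFrame:
    """Tabulate plays (one row per LevelPlay) for export."""
    return pd.DataFrame([
        {"child_id": p.child_id, "session": p.session, "level": p.level,
         "encounter_index": p.encounter_index, "symbols": p.symbols,
         "length": p.length, "n_transitions": p.n_transitions,
         "complete": p.complete}
        for p in plays
    ], columns=["child_id", "session", "level", "encounter_index", "symbols",
                "length", "n_transitions", "complete"])
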