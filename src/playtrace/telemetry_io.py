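"""Reading, validating and writing game-telemetry event logs and cohort tables.

Telemetry arrives as one timestamped record per game event (click).  The
canonical interchange formats are a flat CSV with header
``child_id,session,level,date,time,status[,food_id]`` and an equivalent
JSON-lines dialect.  Cohort outcome tables are CSV; the food taxonomy is a
YAML/JSON mapping ``food_id -> good|bad``.

Timestamps in raw logs use a dash-separated 24-hour clock with millisecond
resolution (``HH-MM-SS-mmm``) plus a ``month/day`` date column; ISO-8601
timestamps are accepted as an alternative dialect.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Mapping, Optional, Sequence, TextIO, Union

import pandas as pd
import yaml

__all__ = [
    "GameEvent",
    "FoodTaxonomy",
    "ChildRecord",
    "RejectedRecord",
    "ParseError",
    "SchemaError",
    "TaxonomyError",
    "EVENT_CLASSES",
    "STATUS_LEVEL_START",
    "STATUS_LEVEL_END",
    "STATUS_FACT_READ",
    "AVATAR_STATUSES",
    "KNOWN_STATUSES",
    "normalize_status",
    "parse_timestamp",
    "read_event_log",
    "write_event_log",
    "load_food_taxonomy",
    "read_cohort_table",
    "write_cohort_table",
]


class ParseError(ValueError):
    """A field of a telemetry record could not be parsed."""


class SchemaError(ValueError):
    """An input file does not conform to the expected schema."""


class TaxonomyError(ValueError):
    """The food taxonomy is inconsistent or incomplete."""


# --------------------------------------------------------------------------
# Event vocabulary
#
# The seven in-level statuses are the game's own event descriptions; the
# fact-read status is the post-level nutrition-fact screen.  How fact reads
# are encoded in raw telemetry is a reconstruction (the upstream backend
# format is not documented), so the status string below is this package's
# canonical spelling.
# --------------------------------------------------------------------------

STATUS_LEVEL_START = "Player starts the level"
STATUS_LEVEL_END = "Player finishes the level"
STATUS_FACT_READ = "Player reads food fact"

AVATAR_STATUSES = (
    "Player consumes good food to generate shield",
    "Robot killed by good food shields",
    "Player shoots bad food ammo",
    "Robot killed by bad food shots",
    "Player hit by bad food robot",
)

KNOWN_STATUSES = (STATUS_LEVEL_START, STATUS_LEVEL_END, *AVATAR_STATUSES, STATUS_FACT_READ)

EVENT_CLASSES = ("level_start", "level_end", "avatar_action", "fact_read")

_WS = re.compile(r"\s+")


def normalize_status(status: str) -> str:
    """Collapse whitespace and case-fold an event description."""
    return _WS.sub(" ", status.strip()).casefold()


_CLASS_BY_STATUS = {normalize_status(STATUS_LEVEL_START): "level_start",
                    normalize_status(STATUS_LEVEL_END): "level_end",
                    normalize_status(STATUS_FACT_READ): "fact_read"}
for _s in AVATAR_STATUSES:
    _CLASS_BY_STATUS[normalize_status(_s)] = "avatar_action"

_CANONICAL_STATUS = {normalize_status(s): s for s in KNOWN_STATUSES}


def classify_status(status: str) -> str:
    """Map an event description to its event class.

    Raises :class:`ParseError` for unrecognized descriptions.
    """
    key = normalize_status(status)
    try:
        return _CLASS_BY_STATUS[key]
    except KeyError:
        raise ParseError(f"unrecognized event status: {status!r}") from None


# --------------------------------------------------------------------------
# Timestamps
# --------------------------------------------------------------------------

#: Year attached to game-dialect dates (logs carry only month/day); any fixed
#: value keeps timestamps totally ordered within a session.
DEFAULT_YEAR = 2019

_TIME_RE = re.compile(r"^(\d{2})-(\d{2})-(\d{2})-(\d{3})$")
_DATE_RE = re.compile(r"^(\d{1,2})/(\d{1,2})$")


def parse_timestamp(time_text: str, date_text: str | None = None, *,
                    year: int = DEFAULT_YEAR, dialect: str = "game") -> datetime:
    """Parse a telemetry clock string into a :class:`datetime`.

    The game dialect is ``HH-MM-SS-mmm`` (24-hour, milliseconds last), e.g.
    ``"09-20-19-775"``; the date column (``month/day``, e.g. ``"7/10"``)
    disambiguates plays that straddle midnight.  With ``dialect="iso"`` the
    time text is handed to :meth:`datetime.fromisoformat` and ``date_text``
    is ignored.
    """
    if dialect == "iso":
        try:
            return datetime.fromisoformat(time_text)
        except ValueError as exc:
            raise ParseError(f"bad ISO timestamp {time_text!r}: {exc}") from None
    if dialect != "game":
        raise ValueError(f"unknown timestamp dialect {dialect!r}")
    m = _TIME_RE.match(time_text.strip())
    if m is None:
        raise ParseError(f"bad time field {time_text!r}: expected HH-MM-SS-mmm")
    hh, mm, ss, ms = (int(g) for g in m.groups())
    month, day = 1, 1
    if date_text is not None and str(date_text).strip():
        dm = _DATE_RE.match(str(date_text).strip())
        if dm is None:
            raise ParseError(f"bad date field {date_text!r}: expected month/day")
        month, day = int(dm.group(1)), int(dm.group(2))
    try:
        return datetime(year, month, day, hh, mm, ss, ms * 1000)
    except ValueError as exc:
        raise ParseError(f"bad timestamp {date_text!r} {time_text!r}: {exc}") from None


def format_timestamp(ts: datetime) -> tuple[str, str]:
    """Render a datetime back into the (date, time) columns of the game dialect."""
    return f"{ts.month}/{ts.day}", f"{ts.hour:02d}-{ts.minute:02d}-{ts.second:02d}-{ts.microsecond // 1000:03d}"


# --------------------------------------------------------------------------
# Domain records
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GameEvent:
    """One timestamped telemetry record.

    ``event_class`` distinguishes level boundaries, in-level avatar actions
    and post-level fact reads; only fact reads carry a ``food_id``.
    """

    child_id: str
    session: int
    level: int
    timestamp: datetime
    status: str
    event_class: str
    food_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.event_class == "fact_read" and not self.food_id:
            raise ValueError("fact_read events must carry a food_id")
        if self.event_class != "fact_read" and self.food_id:
            raise ValueError("only fact_read events may carry a food_id")
        if self.level < 1:
            raise ValueError(f"level must be positive, got {self.level}")


@dataclass(frozen=True)
class RejectedRecord:
    """An input record that failed validation, with its location and reason."""

    line_no: int
    reason: str
    raw: str


@dataclass(frozen=True)
class FoodTaxonomy:
    """Total mapping from food identifier to dietary class (good/bad)."""

    classes: Mapping[str, str]

    def classify(self, food_id: str) -> str:
        try:
            return self.classes[food_id]
        except KeyError:
            raise TaxonomyError(f"food {food_id!r} is not in the taxonomy") from None

    def is_good(self, food_id: str) -> bool:
        return self.classify(food_id) == "good"

    @property
    def good_foods(self) -> tuple[str, ...]:
        return tuple(f for f, c in self.classes.items() if c == "good")

    @property
    def bad_foods(self) -> tuple[str, ...]:
        return tuple(f for f, c in self.classes.items() if c == "bad")

    def __len__(self) -> int:
        return len(self.classes)


def _opt_int(value, lo: int, hi: int, name: str):
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    v = int(value)
    if not lo <= v <= hi:
        raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
    return v


@dataclass
class ChildRecord:
    """Per-child arm assignment and food-choice / food-knowledge outcomes.

    Day outcomes are the number of healthy items chosen (0-2 per day) and
    correctly identified (0-4 per survey); totals pool both days.  ``good_base``
    is the rater-coded binary baseline preference (None when missing).
    """

    child_id: str
    group: str
    school: str
    good_choice_day1: Optional[int] = None
    good_choice_day2: Optional[int] = None
    good_id_day1: Optional[int] = None
    good_id_day2: Optional[int] = None
    good_base: Optional[int] = None
    gender: Optional[str] = None
    bmi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in ("treatment", "control"):
            raise ValueError(f"group must be treatment|control, got {self.group!r}")
        self.good_choice_day1 = _opt_int(self.good_choice_day1, 0, 2, "good_choice_day1")
        self.good_choice_day2 = _opt_int(self.good_choice_day2, 0, 2, "good_choice_day2")
        self.good_id_day1 = _opt_int(self.good_id_day1, 0, 4, "good_id_day1")
        self.good_id_day2 = _opt_int(self.good_id_day2, 0, 4, "good_id_day2")
        self.good_base = _opt_int(self.good_base, 0, 1, "good_base")

    @property
    def good_choice(self) -> Optional[int]:
        """Healthy choices pooled over both days (0-4); None unless both days present."""
        if self.good_choice_day1 is None or self.good_choice_day2 is None:
            return None
        return self.good_choice_day1 + self.good_choice_day2

    @property
    def good_id(self) -> Optional[int]:
        """Healthy identifications pooled over both surveys (0-8)."""
        if self.good_id_day1 is None or self.good_id_day2 is None:
            return None
        return self.good_id_day1 + self.good_id_day2

    @property
    def complete_outcomes(self) -> bool:
        return self.good_choice is not None and self.good_id is not None


# --------------------------------------------------------------------------
# Event-log I/O
# --------------------------------------------------------------------------

EVENT_COLUMNS = ("child_id", "session", "level", "date", "time", "status", "food_id")
_REQUIRED_COLUMNS = ("child_id", "session", "level", "date", "time", "status")

_LEVEL_RE = re.compile(r"^(?:level\s*)?(\d+)$", re.IGNORECASE)


def _parse_level(text) -> int:
    m = _LEVEL_RE.match(str(text).strip())
    if m is None:
        raise ParseError(f"bad level field {text!r}")
    return int(m.group(1))


def _record_to_event(rec: Mapping[str, object], *, year: int, timestamp_dialect: str) -> GameEvent:
    status = str(rec["status"])
    event_class = classify_status(status)
    food_id = rec.get("food_id") or None
    if food_id is not None:
        food_id = str(food_id).strip() or None
    if event_class != "fact_read":
        food_id = None
    return GameEvent(
        child_id=str(rec["child_id"]).strip(),
        session=int(rec["session"]),
        level=_parse_level(rec["level"]),
        timestamp=parse_timestamp(str(rec["time"]), rec.get("date"),
                                  year=year, dialect=timestamp_dialect),
        status=_CANONICAL_STATUS[normalize_status(status)],
        event_class=event_class,
        food_id=food_id,
    )


def _open_maybe(source, mode: str):
    if isinstance(source, (str, Path)):
        return open(source, mode, newline="", encoding="utf-8"), True
    return source, False


def read_event_log(source: Union[str, Path, TextIO], dialect: str = "csv", *,
                   year: int = DEFAULT_YEAR, timestamp_dialect: str = "game",
                   rejects: Optional[list] = None) -> list[GameEvent]:
    """Read a telemetry log and return events sorted for sequence building.

    Events come back ordered by ``(child_id, session, timestamp)`` with the
    input file order as a stable tie-break, so simultaneous records keep the
    log's own ordering.  Records whose status is unrecognized are appended to
    ``rejects`` (as :class:`RejectedRecord`) when a list is supplied;
    otherwise the first such record raises.  Missing required columns raise
    :class:`SchemaError`.
    """
    if dialect not in ("csv", "jsonl"):
        raise ValueError(f"unknown dialect {dialect!r}")
    fh, owned = _open_maybe(source, "r")
    try:
        raw_records: list[tuple[int, Mapping[str, object], str]] = []
        if dialect == "csv":
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in _REQUIRED_COLUMNS if c not in header]
            if missing:
                raise SchemaError(f"event log is missing required columns: {missing}")
            for i, row in enumerate(reader, start=2):
                raw_records.append((i, row, ",".join(str(v) for v in row.values())))
        else:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"line {i}: invalid JSON: {exc}") from None
                missing = [c for c in _REQUIRED_COLUMNS if c not in rec]
                if missing:
                    raise SchemaError(f"line {i}: missing keys: {missing}")
                raw_records.append((i, rec, line.rstrip("\n")))
    finally:
        if owned:
            fh.close()

    events: list[tuple] = []
    for line_no, rec, raw in raw_records:
        try:
            ev = _record_to_event(rec, year=year, timestamp_dialect=timestamp_dialect)
        except ParseError as exc:
            if rejects is None:
                raise
            rejects.append(RejectedRecord(line_no=line_no, reason=str(exc), raw=raw))
            continue
        events.append((ev.child_id, ev.session, ev.timestamp, line_no, ev))
    events.sort(key=lambda t: t[:4])
    return [t[4] for t in events]


def write_event_log(events: Sequence[GameEvent], sink: Union[str, Path, TextIO],
                    dialect: str = "csv") -> int:
    """Write events in the given dialect; returns the record count.

    Output is re-readable by :func:`read_event_log` (round-trip identity on
    valid event lists).
    """
    if dialect not in ("csv", "jsonl"):
        raise ValueError(f"unknown dialect {dialect!r}")
    fh, owned = _open_maybe(sink, "w")
    try:
        n = 0
        if dialect == "csv":
            writer = csv.writer(fh)
            writer.writerow(EVENT_COLUMNS)
            for ev in events:
                date, time = format_timestamp(ev.timestamp)
                writer.writerow([ev.child_id, ev.session, ev.level, date, time,
                                 ev.status, ev.food_id or ""])
                n += 1
        else:
            for ev in events:
                date, time = format_timestamp(ev.timestamp)
                rec = {"child_id": ev.child_id, "session": ev.session, "level": ev.level,
                       "date": date, "time": time, "status": ev.status}
                if ev.food_id:
                    rec["food_id"] = ev.food_id
                fh.write(json.dumps(rec) + "\n")
                n += 1
        return n
    finally:
        if owned:
            fh.close()


# --------------------------------------------------------------------------
# Taxonomy and cohort tables
# --------------------------------------------------------------------------


def load_food_taxonomy(config: Union[str, Path, TextIO, Mapping[str, str]]) -> FoodTaxonomy:
    """Build a :class:`FoodTaxonomy` from a mapping or a YAML/JSON config.

    The config is a flat mapping ``{food_id: good|bad}``, a list of
    single-entry mappings (``- water: good``), or either under a top-level
    ``foods:`` key.  Repeating a food with the same class is idempotent; a
    conflicting repeat raises :class:`TaxonomyError`.
    """
    if isinstance(config, Mapping):
        raw = dict(config)
    elif isinstance(config, list):
        raw = config
    else:
        fh, owned = _open_maybe(config, "r")
        try:
            raw = yaml.safe_load(fh.read()) or {}
        finally:
            if owned:
                fh.close()
    if isinstance(raw, Mapping) and "foods" in raw:
        raw = raw["foods"]
    if isinstance(raw, Mapping):
        entries = list(raw.items())
    else:
        entries = []
        for item in raw:
            if not isinstance(item, Mapping) or len(item) != 1:
                raise TaxonomyError(f"bad taxonomy entry: {item!r}")
            entries.append(next(iter(item.items())))
    classes: dict[str, str] = {}
    for food, cls in entries:
        cls = str(cls).strip().lower()
        if cls not in ("good", "bad"):
            raise TaxonomyError(f"food {food!r} has unknown class {cls!r}")
        prev = classes.get(str(food))
        if prev is not None and prev != cls:
            raise TaxonomyError(f"food {food!r} listed as both {prev!r} and {cls!r}")
        classes[str(food)] = cls
    return FoodTaxonomy(classes=classes)


_COHORT_COLUMNS = ("child_id", "group", "school", "good_choice_day1", "good_choice_day2",
                   "good_id_day1", "good_id_day2", "good_base", "gender", "bmi")


def read_cohort_table(source: Union[str, Path, TextIO]) -> list[ChildRecord]:
    """Read the per-child outcome table (CSV) into :class:`ChildRecord` rows."""
    df = pd.read_csv(source, dtype={"child_id": str, "school": str})
    missing = [c for c in ("child_id", "group", "school") if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table is missing required columns: {missing}")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in _COHORT_COLUMNS:
            if col in df.columns:
                val = row[col]
                kwargs[col] = None if pd.isna(val) else val
        records.append(ChildRecord(**kwargs))
    return records


def write_cohort_table(children: Sequence[ChildRecord], sink: Union[str, Path, TextIO]) -> int:
    """Write ChildRecords as CSV; returns the row count."""
    rows = []
    for c in children:
        rows.append({col: getattr(c, col) for col in _COHORT_COLUMNS})
    df = pd.DataFrame(rows, columns=_COHORT_COLUMNS)
    df.to_csv(sink, index=False)
    return len(rows)


def cohort_to_frame(children: Sequence[ChildRecord]) -> pd.DataFrame:
    """Tabulate ChildRecords with derived pooled outcomes (GoodChoice, GoodID)."""
    rows = []
    for c in children:
        row = {col: getattr(c, col) for col in _COHORT_COLUMNS}
        row["GoodChoice"] = c.good_choice
        row["GoodID"] = c.good_id
        rows.append(row)
    return pd.DataFrame(rows, columns=list(_COHORT_COLUMNS) + ["GoodChoice", "GoodID"])
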