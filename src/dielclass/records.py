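"""Detection-event and trapping-effort data model, I/O and survey-level summaries.

A *detection event* is one camera trigger: the burst of photos a trigger
produces shares the timestamp of its first frame and counts once.  Cameras
impose a refractory delay between consecutive triggers; for general inputs
(and for synthetic surveys) :func:`filter_independent_events` enforces the
same rule in software, retaining an event only if it falls at least the
window length after the last *retained* event of the same camera x species
stream.  Effort is a ledger of closed date intervals per camera; one
camera-day of active effort is one trap-day, the unit that normalizes
detection counts into rates.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .solar import SEASONS

__all__ = [
    "DetectionEvent",
    "EffortLedger",
    "CountSummary",
    "EventParseError",
    "read_events",
    "write_events",
    "read_effort",
    "filter_independent_events",
    "summarize_counts",
    "survey_rate",
]

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ("camera_id", "species", "timestamp")
EFFORT_COLUMNS = ("camera_id", "start_date", "end_date")


class EventParseError(ValueError):
    """A malformed row in an event or effort CSV, carrying its line number."""


@dataclass(frozen=True, order=True)
class DetectionEvent:
    """One independent capture event: a camera trigger for one species."""

    camera_id: str
    species: str
    timestamp: dt.datetime

    def __post_init__(self) -> None:
        if not self.camera_id:
            raise ValueError("camera_id must be non-empty")
        if not self.species:
            raise ValueError("species must be non-empty")


@dataclass
class EffortLedger:
    """Active-date intervals per camera; intervals are closed on both ends.

    An event timestamped anywhere on a boundary date counts as within effort.
    """

    entries: dict[str, list[tuple[dt.date, dt.date]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cam, ivs in self.entries.items():
            ivs.sort()
            for (s0, e0), (s1, _e1) in zip(ivs, ivs[1:]):
                if s1 <= e0:
                    raise ValueError(f"overlapping effort intervals for camera {cam!r}")
            for s, e in ivs:
                if e < s:
                    raise ValueError(f"effort interval for camera {cam!r} ends before it starts")

    @property
    def trap_days(self) -> int:
        """Total camera-days of effort (closed intervals: both endpoints count)."""
        return sum((e - s).days + 1 for ivs in self.entries.values() for s, e in ivs)

    def is_active(self, camera_id: str, date: dt.date) -> bool:
        return any(s <= date <= e for s, e in self.entries.get(camera_id, ()))

    def cameras_active(self, date: dt.date) -> int:
        return sum(1 for cam in self.entries if self.is_active(cam, date))

    def active_dates(self) -> list[dt.date]:
        """Sorted dates with at least one active camera."""
        dates: set[dt.date] = set()
        for ivs in self.entries.values():
            for s, e in ivs:
                dates.update(s + dt.timedelta(days=i) for i in range((e - s).days + 1))
        return sorted(dates)

    def date_span(self) -> tuple[dt.date, dt.date]:
        dates = self.active_dates()
        if not dates:
            raise ValueError("effort ledger is empty")
        return dates[0], dates[-1]


@dataclass
class CountSummary:
    """Event counts per species x season with totals and record percentages."""

    table: pd.DataFrame  # index species, columns seasons + 'total' + 'percent'
    grand_total: int

    @property
    def season_totals(self) -> pd.Series:
        return self.table[list(SEASONS)].sum(axis=0)

    @property
    def species_totals(self) -> pd.Series:
        return self.table["total"]

    @property
    def percentages(self) -> pd.Series:
        return self.table["percent"]

    def mean_events_per_species(self) -> float:
        return float(self.species_totals.mean())


def read_events(path: str | Path) -> list[DetectionEvent]:
    """Read an event CSV (``camera_id, species, timestamp``, ISO-8601 local times).

    Row order is preserved.  A missing column is fatal; a malformed timestamp
    raises :class:`EventParseError` naming the offending line (line 1 is the
    header).
    """
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise EventParseError(f"{path}: missing required column(s) {missing}")
    events: list[DetectionEvent] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            ts = dt.datetime.fromisoformat(str(row.timestamp).strip())
        except ValueError as exc:
            raise EventParseError(
                f"{path}, line {line}: bad timestamp {row.timestamp!r}: {exc}"
            ) from exc
        try:
            events.append(DetectionEvent(str(row.camera_id).strip(),
                                         str(row.species).strip(), ts))
        except ValueError as exc:
            raise EventParseError(f"{path}, line {line}: {exc}") from exc
    logger.info("read %d events from %s", len(events), path)
    return events


def write_events(events: Iterable[DetectionEvent], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(e.camera_id, e.species, e.timestamp.isoformat(sep=" ")) for e in events],
        columns=list(EVENT_COLUMNS),
    )
    frame.to_csv(path, index=False)


def read_effort(path: str | Path) -> EffortLedger:
    """Read an effort CSV (``camera_id, start_date, end_date``, ISO dates, closed)."""
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in EFFORT_COLUMNS if c not in frame.columns]
    if missing:
        raise EventParseError(f"{path}: missing required column(s) {missing}")
    entries: dict[str, list[tuple[dt.date, dt.date]]] = {}
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2
        try:
            start = dt.date.fromisoformat(str(row.start_date).strip())
            end = dt.date.fromisoformat(str(row.end_date).strip())
        except ValueError as exc:
            raise EventParseError(f"{path}, line {line}: bad date: {exc}") from exc
        entries.setdefault(str(row.camera_id).strip(), []).append((start, end))
    ledger = EffortLedger(entries)
    logger.info("read effort for %d cameras (%d trap-days) from %s",
                len(entries), ledger.trap_days, path)
    return ledger


def filter_independent_events(
    events: Sequence[DetectionEvent], window_minutes: float
) -> list[DetectionEvent]:
    """Enforce a refractory window within each camera x species stream.

    An event is retained iff it falls at least ``window_minutes`` after the
    last *retained* event of the same stream (rolling rule, mirroring the
    camera's hardware delay).  The result is sorted by (camera, species,
    time) and the operation is idempotent.
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be positive")
    window = dt.timedelta(minutes=window_minutes)
    retained: list[DetectionEvent] = []
    last_kept: dict[tuple[str, str], dt.datetime] = {}
    for ev in sorted(events):
        key = (ev.camera_id, ev.species)
        prev = last_kept.get(key)
        if prev is None or ev.timestamp - prev >= window:
            retained.append(ev)
            last_kept[key] = ev.timestamp
    logger.info("independence filter (%g min): %d of %d events retained",
                window_minutes, len(retained), len(events))
    return retained


def summarize_counts(
    events: Sequence[DetectionEvent],
    season_of: Callable[[dt.date], str],
) -> CountSummary:
    """Species x season event counts, totals and percentages of all records.

    Percentages are species total / grand total x 100; with no events they
    are undefined and reported as NaN.
    """
    species = sorted({e.species for e in events})
    table = pd.DataFrame(0, index=pd.Index(species, name="species"),
                         columns=list(SEASONS), dtype=int)
    for ev in events:
        table.loc[ev.species, season_of(ev.timestamp.date())] += 1
    table["total"] = table[list(SEASONS)].sum(axis=1)
    grand = int(table["total"].sum())
    if grand > 0:
        table["percent"] = (table["total"] / grand * 100).round(2)
    else:
        table["percent"] = float("nan")
        logger.warning("no events: percentages undefined")
    return CountSummary(table=table, grand_total=grand)


def survey_rate(total_events: int, trap_days: int) -> float:
    """Events per trap-day over the whole survey."""
    if trap_days <= 0:
        raise ValueError("trap_days must be positive")
    return total_events / trap_days
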