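"""Data model for mother-machine lineage observations.

A mother machine traps one cell lineage per dead-end growth channel; after
each division only the cell at the closed end remains observable, so the
sequence of divisions in a channel traces a single mother-daughter chain.
Observations arrive as an *event table*: one row per division, death or
end-of-observation event per channel, with times in hours since the start of
the experiment.

The CSV dialect is ``channel_id,time_h,event`` (UTF-8, header required,
times as decimal hours, events one of ``division``, ``death``,
``end_of_observation``).  Per channel, events must be strictly increasing in
time and a terminal event (death or end_of_observation) must come last.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "EventRecord",
    "CellCycle",
    "LineageSeries",
    "EventTableError",
    "read_events",
    "write_events",
    "extract_cycles",
    "ancestor_descendant_pairs",
    "filter_lineages",
]

DIVISION = "division"
DEATH = "death"
END_OF_OBSERVATION = "end_of_observation"
_EVENT_TYPES = (DIVISION, DEATH, END_OF_OBSERVATION)
_TERMINAL = (DEATH, END_OF_OBSERVATION)


class EventTableError(ValueError):
    """Raised when an event table is malformed or violates its invariants."""


@dataclass(frozen=True)
class EventRecord:
    """One observed event in one growth channel."""

    channel_id: str
    time_h: float
    event: str

    def __post_init__(self) -> None:
        if self.event not in _EVENT_TYPES:
            raise EventTableError(
                f"unknown event type {self.event!r}; expected one of {_EVENT_TYPES}"
            )
        if not self.time_h >= 0:
            raise EventTableError(
                f"event time must be >= 0 h, got {self.time_h!r} "
                f"(channel {self.channel_id!r})"
            )


@dataclass(frozen=True)
class CellCycle:
    """One complete generation: birth (a division) to the next division.

    ``tau_h`` is the generation time (interdivision time) in hours.
    """

    channel_id: str
    generation_index: int
    birth_time_h: float
    division_time_h: float
    tau_h: float

    def __post_init__(self) -> None:
        if not self.tau_h > 0:
            raise EventTableError(
                f"generation time must be > 0, got {self.tau_h} "
                f"(channel {self.channel_id!r})"
            )


@dataclass(frozen=True)
class LineageSeries:
    """Ordered generation-time series of one channel, with its fate."""

    channel_id: str
    taus: tuple[float, ...]
    fate: str  # "alive_at_end" or "died"
    last_observed_time_h: float


def _validate_channel(channel_id: str, records: Sequence[EventRecord]) -> None:
    times = [r.time_h for r in records]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise EventTableError(
            f"channel {channel_id!r}: event times must be strictly increasing"
        )
    terminal = [i for i, r in enumerate(records) if r.event in _TERMINAL]
    if len(terminal) > 1:
        raise EventTableError(
            f"channel {channel_id!r}: more than one terminal "
            f"(death/end_of_observation) event"
        )
    if terminal and terminal[0] != len(records) - 1:
        raise EventTableError(
            f"channel {channel_id!r}: event recorded after the terminal "
            f"{records[terminal[0]].event!r} event"
        )


def validate_events(events: Iterable[EventRecord]) -> dict[str, list[EventRecord]]:
    """Group events by channel, sort by time, and check per-channel invariants.

    Returns a dict mapping channel_id to its time-sorted event list.  Channel
    order follows first appearance in the input.
    """
    by_channel: dict[str, list[EventRecord]] = {}
    for rec in events:
        by_channel.setdefault(rec.channel_id, []).append(rec)
    for cid, recs in by_channel.items():
        recs.sort(key=lambda r: r.time_h)
        _validate_channel(cid, recs)
    return by_channel


def read_events(source) -> list[EventRecord]:
    """Read and validate an event table from a path or text stream.

    Records are returned grouped by channel (in order of first appearance)
    and sorted by time within each channel, so that
    ``write_events(read_events(f))`` is the canonical form of ``f``.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_events(fh)
    reader = csv.reader(source)
    try:
        header = next(reader)
    except StopIteration:
        raise EventTableError("empty event table: missing header row")
    if [h.strip() for h in header] != ["channel_id", "time_h", "event"]:
        raise EventTableError(
            f"bad header {header!r}; expected channel_id,time_h,event"
        )
    records: list[EventRecord] = []
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != 3:
            raise EventTableError(f"line {lineno}: expected 3 fields, got {len(row)}")
        cid, time_s, event = (f.strip() for f in row)
        try:
            time_h = float(time_s)
        except ValueError:
            raise EventTableError(f"line {lineno}: unparseable time {time_s!r}")
        try:
            records.append(EventRecord(cid, time_h, event))
        except EventTableError as exc:
            raise EventTableError(f"line {lineno}: {exc}") from None
    by_channel = validate_events(records)
    return [r for recs in by_channel.values() for r in recs]


def write_events(events: Iterable[EventRecord], dest=None) -> str:
    """Write an event table in canonical form; returns the CSV text.

    If ``dest`` is a path or stream the text is also written there.
    """
    by_channel = validate_events(events)
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["channel_id", "time_h", "event"])
    for recs in by_channel.values():
        for r in recs:
            writer.writerow([r.channel_id, repr(float(r.time_h)), r.event])
    text = buf.getvalue()
    if dest is not None:
        if isinstance(dest, (str, bytes)) or hasattr(dest, "__fspath__"):
            with open(dest, "w", encoding="utf-8", newline="") as fh:
                fh.write(text)
        else:
            dest.write(text)
    return text


def extract_cycles(
    events: Iterable[EventRecord], window_end_h: float | None = None
) -> list[CellCycle]:
    """Extract complete cell cycles (division-to-division spans) per channel.

    Incomplete generations — the segment before the first observed division
    and the segment after the last division (censored by death or by the end
    of observation) — are excluded.  Channels with fewer than two divisions
    therefore yield no cycles.

    ``window_end_h`` optionally restricts divisions to times <= the window
    end; by default all recorded divisions are used.
    """
    by_channel = validate_events(events)
    cycles: list[CellCycle] = []
    for cid, recs in by_channel.items():
        div_times = [
            r.time_h
            for r in recs
            if r.event == DIVISION
            and (window_end_h is None or r.time_h <= window_end_h)
        ]
        for k in range(1, len(div_times)):
            birth, division = div_times[k - 1], div_times[k]
            cycles.append(
                CellCycle(
                    channel_id=cid,
                    generation_index=k,
                    birth_time_h=birth,
                    division_time_h=division,
                    tau_h=division - birth,
                )
            )
    return cycles


def ancestor_descendant_pairs(
    cycles: Iterable[CellCycle], lag: int = 1
) -> list[tuple[float, float]]:
    """All within-channel generation-time pairs (tau_k, tau_{k+lag}).

    Consecutive cycles in a channel are mother and daughter by mother-machine
    geometry, so ``lag=1`` gives mother-daughter pairs and ``lag=10`` pairs a
    cell with its tenth-generation descendant.  A channel with m cycles
    contributes max(0, m - lag) pairs.
    """
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    series = _series_by_channel(cycles)
    pairs: list[tuple[float, float]] = []
    for taus in series.values():
        for k in range(len(taus) - lag):
            pairs.append((taus[k], taus[k + lag]))
    return pairs


def _series_by_channel(cycles: Iterable[CellCycle]) -> dict[str, list[float]]:
    by_channel: dict[str, list[tuple[int, float]]] = {}
    for c in cycles:
        by_channel.setdefault(c.channel_id, []).append((c.generation_index, c.tau_h))
    out: dict[str, list[float]] = {}
    for cid, indexed in by_channel.items():
        indexed.sort(key=lambda p: p[0])
        out[cid] = [tau for _, tau in indexed]
    return out


def filter_lineages(
    cycles: Iterable[CellCycle],
    min_divisions: int = 4,
    events: Iterable[EventRecord] | None = None,
) -> list[LineageSeries]:
    """Retain channels with at least ``min_divisions`` division events.

    A channel with d division events holds d - 1 complete cycles and hence
    d - 2 consecutive (mother-daughter) generation-time pairs, so the default
    threshold of four divisions guarantees at least three complete cycles
    and at least two mother-daughter pairs per retained lineage.

    If the originating ``events`` are supplied, fates (died vs alive at the
    end of observation) and last observed times are taken from them;
    otherwise fate defaults to "alive_at_end" and the last division time.
    """
    if min_divisions < 0:
        raise ValueError("min_divisions must be >= 0")
    cycles = list(cycles)
    series = _series_by_channel(cycles)
    last_division = {
        cid: max(c.division_time_h for c in cycles if c.channel_id == cid)
        for cid in series
    }
    fates: dict[str, tuple[str, float]] = {}
    if events is not None:
        for cid, recs in validate_events(events).items():
            last = recs[-1]
            fate = "died" if last.event == DEATH else "alive_at_end"
            fates[cid] = (fate, last.time_h)
    out: list[LineageSeries] = []
    for cid, taus in series.items():
        n_divisions = len(taus) + 1  # d divisions bound d-1 cycles
        if n_divisions < min_divisions:
            continue
        fate, last_t = fates.get(cid, ("alive_at_end", last_division[cid]))
        out.append(
            LineageSeries(
                channel_id=cid, taus=tuple(taus), fate=fate, last_observed_time_h=last_t
            )
        )
    return out
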