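"""From raw reader events to credible visits, time layers and migrations.

A nest-box stay is only credited when the reader pair fires in the credible
order: outer then inner on the way in, inner then outer on the way out.
Everything else ("equivocal signals") is dropped and counted, never raised.
The record is then cut into time layers: fragments separated by
enclosure-wide silences longer than ``gap_max_hours``, capped at
``layer_max_hours``, with short layers merged into their nearest neighbour.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

from demeflow.io_rfid import DAY, ReaderEvent, RunConfig, SPECIAL_BOXES

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class Visit:
    """A credible nest-box stay."""

    tag_id: str
    box_id: str
    t_enter: float
    t_exit: float

    def __post_init__(self) -> None:
        if not self.t_enter < self.t_exit:
            raise ValueError(f"visit must have t_enter < t_exit, got {self}")
        if self.box_id in SPECIAL_BOXES:
            raise ValueError(f"visit box must be a nest box, got {self.box_id!r}")

    @property
    def duration(self) -> float:
        return self.t_exit - self.t_enter


@dataclasses.dataclass
class TimeLayer:
    """A contiguous record fragment acting as one network snapshot."""

    index: int
    t_start: float
    t_end: float
    visits: list[Visit] = dataclasses.field(default_factory=list)

    @property
    def mid_time_days(self) -> float:
        return (self.t_start + self.t_end) / 2.0 / DAY

    @property
    def span_hours(self) -> float:
        return (self.t_end - self.t_start) / 3600.0


@dataclasses.dataclass
class MigrationEvent:
    tag_id: str
    time: float
    from_enclosure: str
    to_enclosure: str


# ---------------------------------------------------------------------------
# visit extraction

def extract_visits(
    events: Sequence[ReaderEvent],
) -> tuple[list[Visit], int]:
    """Pair dual-reader signals into visits; returns (visits, n_equivocal).

    Per individual: a credible entry is an outer read immediately followed by
    an inner read at the same box (entry time = the inner-read time); a
    credible exit is inner followed by outer (exit time = the outer-read
    time).  An entry is paired with the next exit from the same box; a new
    credible entry before that exit closes the open visit at the new entry's
    inner-read time.  Unpaired signals are dropped and counted.
    """
    by_tag: dict[str, list[ReaderEvent]] = {}
    for ev in events:
        if ev.box_id in SPECIAL_BOXES:
            continue
        by_tag.setdefault(ev.tag_id, []).append(ev)

    visits: list[Visit] = []
    equivocal = 0
    for tag, evs in by_tag.items():
        open_visit: tuple[str, float] | None = None  # (box, t_enter)
        prev: ReaderEvent | None = None
        for ev in evs:
            if prev is None:
                prev = ev
                continue
            if (
                prev.position == "outer"
                and ev.position == "inner"
                and prev.box_id == ev.box_id
            ):
                # credible entry at the inner-read time
                if open_visit is not None:
                    box, t_in = open_visit
                    if t_in < ev.timestamp:
                        visits.append(Visit(tag, box, t_in, ev.timestamp))
                    else:
                        equivocal += 1
                open_visit = (ev.box_id, ev.timestamp)
                prev = None
            elif (
                prev.position == "inner"
                and ev.position == "outer"
                and prev.box_id == ev.box_id
            ):
                # credible exit at the outer-read time
                if open_visit is not None and open_visit[0] == ev.box_id:
                    box, t_in = open_visit
                    if t_in < ev.timestamp:
                        visits.append(Visit(tag, box, t_in, ev.timestamp))
                    else:
                        equivocal += 1
                    open_visit = None
                else:
                    equivocal += 2  # exit pair without a matching entry
                prev = None
            else:
                equivocal += 1  # prev cannot start a credible pair
                prev = ev
        if prev is not None:
            equivocal += 1
        if open_visit is not None:
            equivocal += 1  # entry never closed by record end
    if equivocal:
        logger.info("extract_visits: dropped %d equivocal signal(s)", equivocal)
    visits.sort(key=lambda v: (v.t_enter, v.tag_id, v.box_id))
    return visits, equivocal


# ---------------------------------------------------------------------------
# check censoring

def censor_windows(
    checks: Iterable[tuple[float, float, str]],
) -> list[tuple[float, float]]:
    """Censored intervals: [check start, next midnight after check end)."""
    windows = []
    for start, end, _kind in checks:
        next_midnight = math.ceil(end / DAY) * DAY
        windows.append((start, next_midnight))
    windows.sort()
    return windows


def censor_checks(
    events: Sequence[ReaderEvent],
    checks: Iterable[tuple[float, float, str]],
) -> list[ReaderEvent]:
    """Drop events recorded during or after a check, until the next midnight."""
    windows = censor_windows(checks)
    if not windows:
        return list(events)
    if events:
        t_lo, t_hi = events[0].timestamp, events[-1].timestamp
        for start, end, _ in checks:
            if end < t_lo or start > t_hi:
                logger.warning(
                    "check interval [%s, %s] lies outside the recorded span", start, end
                )
    out = []
    for ev in events:
        if any(s <= ev.timestamp < e for s, e in windows):
            continue
        out.append(ev)
    return out


def clip_visits(
    visits: Iterable[Visit], windows: Sequence[tuple[float, float]]
) -> list[Visit]:
    """Clip visits so every retained visit lies wholly outside censored windows.

    A visit spanning a window is split at the window boundaries.
    """
    out = []
    for v in visits:
        pieces = [(v.t_enter, v.t_exit)]
        for s, e in windows:
            nxt = []
            for a, b in pieces:
                if b <= s or a >= e:
                    nxt.append((a, b))
                    continue
                if a < s:
                    nxt.append((a, s))
                if b > e:
                    nxt.append((e, b))
            pieces = nxt
        for a, b in pieces:
            if a < b:
                out.append(Visit(v.tag_id, v.box_id, a, b))
    return out


# ---------------------------------------------------------------------------
# time layers

def build_time_layers(
    events: Sequence[ReaderEvent], config: RunConfig | None = None
) -> list[TimeLayer]:
    """Cut the censored record into time layers.

    1. split at every enclosure-wide silent gap > ``gap_max_hours``;
    2. split fragments longer than ``layer_max_hours`` into consecutive
       pieces measured from the fragment start;
    3. iteratively merge any layer whose first-to-last-event span is below
       ``layer_min_hours_for_merge`` with its nearest neighbour (smaller
       inter-layer gap, ties to the earlier one) until none remains or a
       single layer is left.
    """
    config = config or RunConfig()
    if not events:
        raise ValueError("no events after censoring")
    times = [ev.timestamp for ev in events]
    gap_s = config.gap_max_hours * 3600.0
    cap_s = config.layer_max_hours * 3600.0
    min_s = config.layer_min_hours_for_merge * 3600.0

    # 1. gap split: fragments as lists of event times
    fragments: list[list[float]] = [[times[0]]]
    for t in times[1:]:
        if t - fragments[-1][-1] > gap_s:
            fragments.append([t])
        else:
            fragments[-1].append(t)

    # 2. cap split at multiples of cap_s from fragment start; piece extents
    # re-anchor to the events each piece actually contains
    pieces: list[tuple[float, float]] = []
    for frag in fragments:
        t0, t1 = frag[0], frag[-1]
        if t1 - t0 <= cap_s:
            pieces.append((t0, t1))
            continue
        bins: dict[int, list[float]] = {}
        for t in frag:
            k = int((t - t0) // cap_s)
            if t == t1 and (t - t0) % cap_s == 0:
                k -= 1  # fragment's last event closes the final piece
            bins.setdefault(k, []).append(t)
        for k in sorted(bins):
            inside = bins[k]
            pieces.append((inside[0], inside[-1]))

    # 3. merge short layers
    pieces = sorted(set(pieces))
    while len(pieces) > 1:
        spans = [hi - lo for lo, hi in pieces]
        short = [i for i, s in enumerate(spans) if s < min_s]
        if not short:
            break
        i = min(short, key=lambda k: spans[k])  # shortest first, for determinism
        if i == 0:
            j = 1
        elif i == len(pieces) - 1:
            j = i - 1
        else:
            gap_prev = pieces[i][0] - pieces[i - 1][1]
            gap_next = pieces[i + 1][0] - pieces[i][1]
            j = i - 1 if gap_prev <= gap_next else i + 1
        a, b = sorted((i, j))
        merged = (pieces[a][0], pieces[b][1])
        pieces = pieces[:a] + [merged] + pieces[b + 1 :]

    return [TimeLayer(index=k, t_start=lo, t_end=hi) for k, (lo, hi) in enumerate(pieces)]


def slice_visits_into_layers(
    layers: Sequence[TimeLayer], visits: Iterable[Visit]
) -> list[TimeLayer]:
    """Attach visits to layers, clipping a visit to each layer's extent.

    A visit spanning a layer boundary is split and its time apportioned to
    each layer, preserving total co-occupancy time.
    """
    for ly in layers:
        ly.visits = []
    for v in visits:
        for ly in layers:
            a = max(v.t_enter, ly.t_start)
            b = min(v.t_exit, ly.t_end)
            if a < b:
                ly.visits.append(Visit(v.tag_id, v.box_id, a, b))
    return list(layers)


# ---------------------------------------------------------------------------
# migrations

def detect_migrations(
    events: Sequence[ReaderEvent],
) -> tuple[list[MigrationEvent], int]:
    """Inter-enclosure movements, plus the count of unrealised attempts.

    A migration is a consecutive pair of same-individual events with
    differing enclosure ids (any reader proves presence).  A tube-reader hit
    whose next same-individual record stays in the same enclosure (or that
    ends the record) counts as an attempt, not a migration.
    """
    by_tag: dict[str, list[ReaderEvent]] = {}
    for ev in events:
        by_tag.setdefault(ev.tag_id, []).append(ev)
    migrations: list[MigrationEvent] = []
    attempts = 0
    for tag, evs in by_tag.items():
        for prev, cur in zip(evs[:-1], evs[1:]):
            if prev.enclosure_id != cur.enclosure_id:
                migrations.append(
                    MigrationEvent(tag, cur.timestamp, prev.enclosure_id, cur.enclosure_id)
                )
            elif prev.box_id in SPECIAL_BOXES and prev.box_id.startswith("connector"):
                attempts += 1
        last = evs[-1]
        if last.box_id in SPECIAL_BOXES and last.box_id.startswith("connector"):
            attempts += 1
    migrations.sort(key=lambda m: (m.time, m.tag_id))
    return migrations, attempts
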