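"""Occupancy-interval algebra over the raw IN/OUT event stream.

The RFID platform logs only *changes* of detection state, so presence must
be reconstructed: each IN opens a per-(animal, antenna) interval and the
matching OUT closes it.  Because an animal can register on the next antenna
before the previous antenna logs its exit (the "doubling" phenomenon),
intervals of one animal on *different* antennas may overlap briefly; that
overlap is retained, not treated as an error.

An animal counts as *detected* at an instant iff at least one of its
intervals is open there — the log records no heartbeat, so a resting animal
(last event IN) is continuously detected until its OUT.  An animal inside
the running wheel is invisible to every antenna, which is exactly the gap
the assignment rule exploits.

Field changes — the package's surrogate for spontaneous cage activity — are
counted on IN events alone: consecutive INs on differing antennas count one
change each, which removes the doubled counts that naive row-difference
counting produces (OUT rows and repeated INs on the same antenna contribute
nothing).
"""

from __future__ import annotations

import logging
from datetime import datetime
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import AntennaEvent, DetectionState, Direction, OccupancyInterval

logger = logging.getLogger(__name__)

_OPEN_MS = np.iinfo(np.int64).max  # sentinel end for still-open intervals


def to_ms(ts: datetime) -> int:
    """Naive local timestamp -> integer milliseconds (exact comparisons)."""
    return pd.Timestamp(ts).value // 1_000_000


def from_ms(ms: int) -> datetime:
    return pd.Timestamp(ms * 1_000_000).to_pydatetime()


class AnomalousEventError(ValueError):
    """Raised in strict mode for events the reconstruction cannot place."""


class Occupancy:
    """Per-animal occupancy intervals with indexed point/range queries."""

    def __init__(self, by_animal: dict[str, list[OccupancyInterval]]):
        self.by_animal = by_animal
        self._closed: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._argmax_start: dict[str, np.ndarray] = {}

    @property
    def animals(self) -> list[str]:
        return sorted(self.by_animal)

    def intervals(self, animal_id: str) -> list[OccupancyInterval]:
        return self.by_animal.get(animal_id, [])

    # -- indexed views -----------------------------------------------------

    def _closed_arrays(self, animal_id):
        """(ends, starts, antennas) of closed intervals, sorted by (end, start)."""
        if animal_id not in self._closed:
            closed = [iv for iv in self.intervals(animal_id) if not iv.is_open]
            closed.sort(key=lambda iv: (to_ms(iv.end), to_ms(iv.start)))
            self._closed[animal_id] = (
                np.array([to_ms(iv.end) for iv in closed], dtype=np.int64),
                np.array([to_ms(iv.start) for iv in closed], dtype=np.int64),
                np.array([iv.antenna for iv in closed], dtype=np.int64),
            )
        return self._closed[animal_id]

    def _merged_arrays(self, animal_id):
        """Union of the animal's intervals over all antennas, as disjoint
        half-open [start, end) runs; open intervals extend to +inf."""
        if animal_id not in self._merged:
            ivs = sorted(
                (
                    (to_ms(iv.start), _OPEN_MS if iv.is_open else to_ms(iv.end))
                    for iv in self.intervals(animal_id)
                ),
            )
            starts: list[int] = []
            ends: list[int] = []
            for s, e in ivs:
                if starts and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            self._merged[animal_id] = (
                np.array(starts, dtype=np.int64),
                np.array(ends, dtype=np.int64),
            )
        return self._merged[animal_id]

    # -- queries -----------------------------------------------------------

    def is_detected(self, animal_id: str, at: datetime) -> bool:
        starts, ends = self._merged_arrays(animal_id)
        t = to_ms(at)
        i = int(np.searchsorted(starts, t, side="right")) - 1
        return i >= 0 and t < ends[i]

    def last_closed(
        self, animal_id: str, at: datetime
    ) -> Optional[tuple[int, int]]:
        """(antenna, end_ms) of the latest interval closed at or before ``at``
        (ties on end broken by later start), or None."""
        ends, _starts, antennas = self._closed_arrays(animal_id)
        i = int(np.searchsorted(ends, to_ms(at), side="right")) - 1
        if i < 0:
            return None
        return int(antennas[i]), int(ends[i])

    def last_entered(
        self, animal_id: str, at: datetime
    ) -> Optional[tuple[int, int]]:
        """(antenna, end_ms) of the most recently *entered* field among the
        intervals closed by ``at`` — selected by latest start, not latest
        end.  The two differ when the doubling lag makes the previous
        antenna's exit register after the next antenna's, which matters for
        deciding which field an animal vanished from."""
        ends, starts, antennas = self._closed_arrays(animal_id)
        i = int(np.searchsorted(ends, to_ms(at), side="right")) - 1
        if i < 0:
            return None
        if animal_id not in self._argmax_start:
            # running argmax of start over the (end, start)-sorted order
            idx = np.arange(len(starts))
            best = np.maximum.accumulate(starts)
            am = np.where(starts == best, idx, 0)
            self._argmax_start[animal_id] = np.maximum.accumulate(am)
        j = int(self._argmax_start[animal_id][i])
        return int(antennas[j]), int(ends[j])

    def detection_state(self, animal_id: str, at: datetime) -> DetectionState:
        last = self.last_closed(animal_id, at)
        return DetectionState(
            animal_id=animal_id,
            at=at,
            detected=self.is_detected(animal_id, at),
            last_closed_antenna=None if last is None else last[0],
        )

    def detected_ms(self, animal_id: str, start: datetime, end: datetime) -> int:
        """Milliseconds of [start, end) during which the animal is detected."""
        starts, ends = self._merged_arrays(animal_id)
        t0, t1 = to_ms(start), to_ms(end)
        lo = np.minimum(np.maximum(starts, t0), t1)
        hi = np.minimum(np.maximum(ends, t0), t1)
        return int(np.sum(hi - lo))

    def first_gap_start(
        self, animal_id: str, start: datetime, end: datetime
    ) -> Optional[int]:
        """First instant in [start, end) at which the animal is undetected,
        in ms, or None if it is detected throughout."""
        starts, ends = self._merged_arrays(animal_id)
        t0, t1 = to_ms(start), to_ms(end)
        t = t0
        i = int(np.searchsorted(starts, t, side="right")) - 1
        if i >= 0 and t < ends[i]:
            t = int(ends[i])  # skip the run covering t0
        # merged runs are disjoint and sorted: runs starting exactly at t
        # extend the covered prefix
        j = i + 1
        while j < len(starts) and starts[j] <= t:
            t = max(t, int(ends[j]))
            j += 1
        return t if t < t1 else None


def build_occupancy(
    events: Sequence[AntennaEvent], strict: bool = False
) -> Occupancy:
    """Reconstruct per-animal occupancy intervals from an ordered event stream.

    Each IN opens an interval on (animal, antenna); the matching OUT closes
    it.  An IN on a second antenna while the first is still open is legal
    (doubling).  Anomalies — an OUT with no open interval, or a repeated IN
    on an already-open (animal, antenna) — are logged and skipped, or raise
    :class:`AnomalousEventError` when ``strict`` (repeated INs are always
    merely ignored, matching the instrument's change-log semantics).
    """
    open_at: dict[tuple[str, int], datetime] = {}
    by_animal: dict[str, list[OccupancyInterval]] = {}
    prev_ts: Optional[datetime] = None
    for i, ev in enumerate(events):
        if prev_ts is not None and ev.timestamp < prev_ts:
            raise AnomalousEventError(
                f"event {i} timestamp {ev.timestamp} precedes {prev_ts}; "
                "the stream must be time-ordered"
            )
        prev_ts = ev.timestamp
        key = (ev.animal_id, ev.antenna)
        if ev.direction is Direction.IN:
            if key in open_at:
                logger.warning(
                    "repeated IN for animal %s on antenna %d at %s ignored",
                    ev.animal_id, ev.antenna, ev.timestamp,
                )
                continue
            open_at[key] = ev.timestamp
        else:
            if key not in open_at:
                msg = (
                    f"OUT with no open interval for animal {ev.animal_id} on "
                    f"antenna {ev.antenna} at {ev.timestamp}"
                )
                if strict:
                    raise AnomalousEventError(msg)
                logger.warning("%s; skipped", msg)
                continue
            start = open_at.pop(key)
            by_animal.setdefault(ev.animal_id, []).append(
                OccupancyInterval(
                    animal_id=ev.animal_id,
                    antenna=ev.antenna,
                    start=start,
                    end=ev.timestamp,
                )
            )
    for (animal_id, antenna), start in open_at.items():
        by_animal.setdefault(animal_id, []).append(
            OccupancyInterval(animal_id=animal_id, antenna=antenna, start=start)
        )
    for ivs in by_animal.values():
        ivs.sort(key=lambda iv: (iv.start, iv.end or datetime.max))
    return Occupancy(by_animal)


def detection_state(
    occupancy: Occupancy, animal_id: str, at: datetime
) -> DetectionState:
    """Convenience wrapper around :meth:`Occupancy.detection_state`."""
    return occupancy.detection_state(animal_id, at)


def in_sequence(
    events: Iterable[AntennaEvent], animal_id: str
) -> tuple[np.ndarray, np.ndarray]:
    """(timestamps_ms, antennas) of one animal's IN events, in stream order."""
    ts, ant = [], []
    for ev in events:
        if ev.animal_id == animal_id and ev.direction is Direction.IN:
            ts.append(to_ms(ev.timestamp))
            ant.append(ev.antenna)
    return np.array(ts, dtype=np.int64), np.array(ant, dtype=np.int64)


def field_changes(
    events: Sequence[AntennaEvent],
    animal_id: str,
    window: Optional[tuple[datetime, datetime]] = None,
    carry_state: bool = False,
) -> int:
    """Deduplicated field-change count for one animal in ``[t_a, t_b)``.

    Only IN events are considered; each consecutive pair of INs with
    differing antenna labels counts one change.  OUT rows and repeated INs
    on the same antenna contribute nothing, which is what removes the
    doubling artefact of naive row counting.

    With ``carry_state`` the animal's last IN before the window also pairs
    with the first IN inside it; by default windows are independent.
    """
    ts, ant = in_sequence(events, animal_id)
    if ts.size == 0:
        logger.warning("no IN events for animal %r", animal_id)
        return 0
    if window is None:
        lo, hi = 0, ts.size
    else:
        lo = int(np.searchsorted(ts, to_ms(window[0]), side="left"))
        hi = int(np.searchsorted(ts, to_ms(window[1]), side="left"))
    if hi <= lo:
        return 0
    inside = ant[lo:hi]
    count = int(np.count_nonzero(inside[1:] != inside[:-1]))
    if carry_state and lo > 0 and inside[0] != ant[lo - 1]:
        count += 1
    return count
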