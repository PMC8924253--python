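"""Shared helpers: random legal event streams and independent oracles.

The oracles deliberately avoid the package's interval machinery: occupancy
is cross-checked against a per-millisecond replay of the raw stream, and
field changes against a naive collapse-and-count of the position sequence.
"""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np

from scave.occupancy import to_ms
from scave.types import AntennaEvent, Direction

EPOCH = datetime(2022, 3, 1)


def ms_to_dt(ms: int) -> datetime:
    return EPOCH + timedelta(milliseconds=int(ms))


def random_legal_stream(
    rng: np.random.Generator,
    n_events: int = 200,
    n_animals: int = 3,
    span_ms: int = 3000,
    cage: str = "1",
) -> list[AntennaEvent]:
    """Random time-ordered stream where every OUT matches an open IN.

    Overlapping intervals on different antennas (doubling) arise naturally;
    intervals left open at the end are legal.
    """
    animals = [chr(ord("A") + i) for i in range(n_animals)]
    open_sets: dict[str, set[int]] = {a: set() for a in animals}
    in_time: dict[tuple[str, int], int] = {}
    times = np.sort(rng.integers(0, span_ms, size=n_events))
    events: list[AntennaEvent] = []
    for t in times:
        a = animals[int(rng.integers(n_animals))]
        opened = sorted(open_sets[a])
        closable = bool(opened)
        openable = len(opened) < 6
        if closable and (not openable or rng.random() < 0.5):
            ant = opened[int(rng.integers(len(opened)))]
            open_sets[a].discard(ant)
            events.append(
                AntennaEvent(
                    timestamp=ms_to_dt(t),
                    cage_id=cage,
                    animal_id=a,
                    antenna=ant,
                    direction=Direction.OUT,
                    dwell_ms=int(t) - in_time.pop((a, ant)),
                )
            )
        else:
            choices = sorted(set(range(1, 7)) - open_sets[a])
            ant = choices[int(rng.integers(len(choices)))]
            open_sets[a].add(ant)
            in_time[(a, ant)] = int(t)
            events.append(
                AntennaEvent(
                    timestamp=ms_to_dt(t),
                    cage_id=cage,
                    animal_id=a,
                    antenna=ant,
                    direction=Direction.IN,
                )
            )
    return events


def brute_force_detected(
    events: list[AntennaEvent], span_ms: int
) -> dict[str, np.ndarray]:
    """Per-animal boolean array: detected on >= 1 antenna at each millisecond.

    Replays the stream one event at a time, holding the per-(animal,
    antenna) open/closed state constant between events — the same
    change-log semantics the interval builder must reproduce.
    """
    animals = sorted({e.animal_id for e in events})
    out = {a: np.zeros(span_ms, dtype=bool) for a in animals}
    open_sets: dict[str, set[int]] = {a: set() for a in animals}
    prev_ms = 0
    for e in events:
        t = to_ms(e.timestamp) - to_ms(EPOCH)
        for a in animals:
            if open_sets[a]:
                out[a][prev_ms:t] = True
        prev_ms = t
        if e.direction is Direction.IN:
            open_sets[e.animal_id].add(e.antenna)
        else:
            open_sets[e.animal_id].discard(e.antenna)
    for a in animals:
        if open_sets[a]:
            out[a][prev_ms:] = True
    return out


def brute_force_on_antenna(
    events: list[AntennaEvent], span_ms: int
) -> dict[tuple[str, int], np.ndarray]:
    """Like :func:`brute_force_detected` but per (animal, antenna)."""
    keys = sorted({(e.animal_id, e.antenna) for e in events})
    out = {k: np.zeros(span_ms, dtype=bool) for k in keys}
    is_open: dict[tuple[str, int], bool] = {k: False for k in keys}
    prev_ms = 0
    for e in events:
        t = to_ms(e.timestamp) - to_ms(EPOCH)
        for k, flag in is_open.items():
            if flag:
                out[k][prev_ms:t] = True
        prev_ms = t
        is_open[(e.animal_id, e.antenna)] = e.direction is Direction.IN
    for k, flag in is_open.items():
        if flag:
            out[k][prev_ms:] = True
    return out


def naive_field_changes(events, animal_id: str, t0=None, t1=None) -> int:
    """Collapse the animal's IN-position sequence and count transitions."""
    positions = [
        e.antenna
        for e in events
        if e.animal_id == animal_id
        and e.direction is Direction.IN
        and (t0 is None or e.timestamp >= t0)
        and (t1 is None or e.timestamp < t1)
    ]
    collapsed = [p for i, p in enumerate(positions) if i == 0 or p != positions[i - 1]]
    return max(0, len(collapsed) - 1)


def insert_random_outs(
    rng: np.random.Generator, events: list[AntennaEvent]
) -> list[AntennaEvent]:
    """Interleave arbitrary extra OUT rows while keeping time order."""
    if not events:
        return events
    out = list(events)
    n_extra = int(rng.integers(1, max(2, len(events) // 2)))
    t_max = to_ms(events[-1].timestamp) - to_ms(EPOCH) + 100
    for _ in range(n_extra):
        t = int(rng.integers(0, t_max))
        out.append(
            AntennaEvent(
                timestamp=ms_to_dt(t),
                cage_id="1",
                animal_id=chr(ord("A") + int(rng.integers(3))),
                antenna=int(rng.integers(1, 7)),
                direction=Direction.OUT,
                dwell_ms=int(rng.integers(0, 1000)),
            )
        )
    out.sort(key=lambda e: e.timestamp)
    return out
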