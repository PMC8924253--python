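"""Synthetic cage simulator with full ground truth.

No public recordings of the two instrument streams exist, so every other
module is validated against this generator.  It emulates a group-housed cage
on a 2x3 grid of RFID antenna fields with a running wheel standing on two of
them, and reproduces the detection semantics that the attribution rule
relies on: an animal inside the wheel is invisible to every antenna, so
entering the wheel logs an OUT on the wheel antenna and leaving it logs an
IN there.

Movement is a continuous-time Markov walk on the grid: exponential holding
times with a dark/light-dependent crossing rate, jumps to a uniformly chosen
adjacent field.  Each antenna crossing registers the next field slightly
*before* the previous field logs its exit (the "doubling" artefact of the
real platform), which exercises the deduplicated field-change counter.
Wheel bouts start at a dark/light-dependent rate while the animal sits on a
wheel antenna, with log-normal durations and normal speeds.  Two confounds
can be injected: a bystander that slips under the wheel and goes undetected
during someone else's bout (``p_bystander``), and human-artifact rotation
minutes with no animal in the wheel (``p_artifact_minute``).

Everything is driven by one seeded generator; the same seed reproduces the
streams byte-for-byte.
"""

from __future__ import annotations

import heapq
from bisect import bisect_right
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import Optional

import numpy as np

from .types import (
    AntennaEvent,
    AssignmentResult,
    Direction,
    Reason,
    Status,
    WheelMinuteRecord,
)

MS_PER_HOUR = 3_600_000
MS_PER_DAY = 86_400_000
MS_PER_MIN = 60_000

#: cage grid: two rows of three antenna fields
GRID = ((1, 2, 3), (4, 5, 6))


def _grid_neighbors(grid=GRID) -> dict[int, tuple[int, ...]]:
    pos = {lab: (r, c) for r, row in enumerate(grid) for c, lab in enumerate(row)}
    nbrs: dict[int, list[int]] = {lab: [] for lab in pos}
    for lab, (r, c) in pos.items():
        for lab2, (r2, c2) in pos.items():
            if abs(r - r2) + abs(c - c2) == 1:
                nbrs[lab].append(lab2)
    return {lab: tuple(sorted(v)) for lab, v in nbrs.items()}


NEIGHBORS = _grid_neighbors()


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one simulated cage.

    Rates are per hour; the defaults describe 4 mice on a 12 h/12 h cycle
    with roughly 2400 antenna crossings per animal per day and a 3:1
    dark:light activity ratio, with nightly wheel use when on a wheel field.
    """

    n_animals: int = 4
    duration_days: float = 7.0
    seed: int = 0
    start: datetime = datetime(2022, 3, 1)
    cage_id: str = "1"
    wheel_antennas: frozenset[int] = frozenset({1, 2})
    light_on: time = time(6, 0)
    light_off: time = time(18, 0)
    move_rate_dark: float = 150.0  # antenna crossings / h
    move_rate_light: float = 50.0
    wheel_bout_rate: float = 2.0  # bouts / h while on a wheel antenna (light)
    wheel_bout_dark_multiplier: float = 4.0
    bout_duration_median_s: float = 75.0
    bout_duration_sigma: float = 0.6  # log-normal shape
    bout_duration_max_s: float = 600.0
    bout_speed_mean_rpm: float = 40.0
    bout_speed_sd_rpm: float = 10.0
    p_bystander: float = 0.0
    p_artifact_minute: float = 0.0
    artifact_rot_max: int = 8
    doubling_lag_ms: tuple[int, int] = (50, 500)

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("need at least one animal")
        if self.duration_days <= 0:
            raise ValueError("duration must be positive")
        for name in ("move_rate_dark", "move_rate_light", "wheel_bout_rate",
                     "wheel_bout_dark_multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_bystander", "p_artifact_minute"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.wheel_antennas <= set(NEIGHBORS):
            raise ValueError("wheel_antennas must be grid labels")

    @property
    def horizon_ms(self) -> int:
        return int(round(self.duration_days * MS_PER_DAY))

    @property
    def n_minutes(self) -> int:
        return self.horizon_ms // MS_PER_MIN

    def animal_ids(self) -> list[str]:
        if self.n_animals <= 26:
            return [chr(ord("A") + i) for i in range(self.n_animals)]
        return [f"M{i + 1:03d}" for i in range(self.n_animals)]

    # -- clock helpers (all in ms since cfg.start) -------------------------

    def _clock_ms(self, t_ms: int) -> int:
        off = (self.start.hour * 3600 + self.start.minute * 60
               + self.start.second) * 1000
        return (off + t_ms) % MS_PER_DAY

    def is_light(self, t_ms: int) -> bool:
        on = (self.light_on.hour * 3600 + self.light_on.minute * 60) * 1000
        off = (self.light_off.hour * 3600 + self.light_off.minute * 60) * 1000
        c = self._clock_ms(t_ms)
        return on <= c < off

    def next_phase_change(self, t_ms: int) -> int:
        on = (self.light_on.hour * 3600 + self.light_on.minute * 60) * 1000
        off = (self.light_off.hour * 3600 + self.light_off.minute * 60) * 1000
        c = self._clock_ms(t_ms)
        deltas = [(b - c) % MS_PER_DAY for b in (on, off)]
        step = min(d for d in deltas if d > 0) if any(d > 0 for d in deltas) \
            else MS_PER_DAY
        return t_ms + step

    def move_rate(self, t_ms: int) -> float:
        return self.move_rate_light if self.is_light(t_ms) else self.move_rate_dark

    def bout_rate(self, t_ms: int) -> float:
        r = self.wheel_bout_rate
        return r if self.is_light(t_ms) else r * self.wheel_bout_dark_multiplier


@dataclass(frozen=True)
class Bout:
    animal_id: str
    start_ms: int
    dur_ms: int
    speed_rpm: float
    right: bool


@dataclass
class GroundTruth:
    """The simulator's complete record of what actually happened."""

    config: SimConfig
    #: per animal: (antenna, in_ms, out_ms or None) detection segments
    segments: dict[str, list[tuple[int, int, Optional[int]]]]
    #: per animal: (enter_ms, exit_ms, exercising) *observable* spells inside
    #: the wheel zone — the spell starts once every lagged registration of a
    #: previously occupied antenna has expired
    wheel_periods: dict[str, list[tuple[int, int, bool]]]
    bouts: list[Bout]
    #: minute index -> artifact rotations injected there
    artifact_minutes: dict[int, int] = field(default_factory=dict)
    #: per animal: (t_ms, position) change points; position 0 = in wheel zone
    path: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def minute_of(self, t_ms: int) -> int:
        return t_ms // MS_PER_MIN

    def exercisers(self, minute: int) -> frozenset[str]:
        """Animals observably running in the wheel during the minute."""
        m0, m1 = minute * MS_PER_MIN, (minute + 1) * MS_PER_MIN
        out = set()
        for animal, periods in self.wheel_periods.items():
            for s, e, exercising in periods:
                if exercising and s < m1 and e > m0:
                    out.add(animal)
                    break
        return frozenset(out)

    def wheel_occupants(self, minute: int) -> frozenset[str]:
        """Animals inside the wheel zone (running or hiding) during the minute."""
        m0, m1 = minute * MS_PER_MIN, (minute + 1) * MS_PER_MIN
        out = set()
        for animal, periods in self.wheel_periods.items():
            for s, e, _ex in periods:
                if s < m1 and e > m0:
                    out.add(animal)
                    break
        return frozenset(out)

    def position(self, animal_id: str, t_ms: int) -> Optional[int]:
        """True position: antenna label, 0 for in-wheel, None before start."""
        pts = self.path.get(animal_id, [])
        i = bisect_right(pts, (t_ms, float("inf"))) - 1
        return None if i < 0 else pts[i][1]

    def expected_assignment(self, minute: int, rot_total: int) -> AssignmentResult:
        """What a correct attribution must report for this wheel-active minute."""
        occupants = self.wheel_occupants(minute)
        start = self.config.start + timedelta(minutes=minute)
        if not occupants:
            return AssignmentResult(
                start, rot_total, frozenset(), Status.DISCARDED, Reason.NO_CANDIDATE
            )
        status = Status.ASSIGNED if len(occupants) == 1 else Status.ASSIGNED_MULTI
        return AssignmentResult(start, rot_total, occupants, status)


@dataclass
class SimResult:
    events: list[AntennaEvent]
    ve: list[WheelMinuteRecord]
    truth: GroundTruth


# -- internal discrete-event machinery --------------------------------------

_MOVE, _BOUT, _WHEEL_END, _B_ARRIVE, _B_HIDE, _B_RETURN = range(6)
_ANT, _WHEEL, _SCRIPT = range(3)


class _Animal:
    __slots__ = ("aid", "antenna", "mode", "gen", "segments", "wheel_periods",
                 "path", "pending", "hide_start")

    def __init__(self, aid: str, antenna: int):
        self.aid = aid
        self.antenna = antenna
        self.mode = _ANT
        self.gen = 0
        self.hide_start = 0
        # finalized (antenna, in_ms, out_ms|None); pending: [antenna, in_ms, out_ms]
        self.segments: list[tuple[int, int, Optional[int]]] = []
        self.pending: list[list] = [[antenna, 0, None]]
        self.wheel_periods: list[tuple[int, int, bool]] = []
        self.path: list[tuple[int, int]] = [(0, antenna)]

    def open_segment(self, antenna: int, t: int) -> None:
        # a lagged OUT on this antenna still pending would overlap the new
        # IN; clamp it to just before the re-entry instant
        for seg in self.pending:
            if seg[0] == antenna and (seg[2] is None or seg[2] >= t):
                seg[2] = max(t - 1, seg[1])
        self._flush(t)
        self.pending.append([antenna, t, None])
        self.antenna = antenna

    def close_current(self, t: int) -> None:
        """Schedule the OUT of the currently occupied antenna at time t."""
        for seg in reversed(self.pending):
            if seg[0] == self.antenna and seg[2] is None:
                seg[2] = t
                return

    def vanish_time(self, t: int) -> int:
        """First instant at or after ``t`` with no registration left.

        A doubling-lagged exit of the previous antenna can outlive the
        wheel-entry OUT by up to the lag, keeping the animal nominally
        detected for the first moments of a wheel spell."""
        return max([t] + [seg[2] for seg in self.pending
                          if seg[2] is not None and seg[2] > t])

    def _flush(self, now: int) -> None:
        keep = []
        for seg in self.pending:
            if seg[2] is not None and seg[2] <= now:
                self.segments.append((seg[0], seg[1], seg[2]))
            else:
                keep.append(seg)
        self.pending = keep

    def finish(self, horizon: int) -> None:
        for seg in self.pending:
            out = seg[2]
            if out is not None and out < horizon:
                self.segments.append((seg[0], seg[1], out))
            else:
                self.segments.append((seg[0], seg[1], None))
        self.pending = []
        self.segments.sort(key=lambda s: (s[1], s[0]))


def _sample_next(cfg: SimConfig, rng: np.random.Generator, t: int,
                 on_wheel: bool) -> Optional[tuple[int, int]]:
    """Next (time_ms, kind) for a freely moving animal, or None past horizon."""
    horizon = cfg.horizon_ms
    while t < horizon:
        mr = cfg.move_rate(t)
        br = cfg.bout_rate(t) if on_wheel else 0.0
        total = mr + br
        boundary = min(cfg.next_phase_change(t), horizon)
        if total <= 0:
            t = boundary
            continue
        dt = rng.exponential(MS_PER_HOUR / total)
        if t + dt >= boundary:
            t = boundary
            continue
        t_next = int(round(t + dt))
        t_next = max(t_next, t + 1)
        if t_next >= boundary:
            t = boundary
            continue
        kind = _MOVE if rng.random() < mr / total else _BOUT
        return t_next, kind
    return None


def simulate_cage(config: SimConfig) -> SimResult:
    """Run one cage and return (SCA events, VE minutes, ground truth)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    horizon = cfg.horizon_ms
    ids = cfg.animal_ids()
    animals = {
        aid: _Animal(aid, int(rng.integers(1, 7))) for aid in ids
    }
    bouts: list[Bout] = []

    heap: list[tuple[int, int, str, int, int, tuple]] = []
    seq = 0

    def push(t: int, aid: str, kind: int, payload: tuple = ()) -> None:
        nonlocal seq
        heapq.heappush(heap, (t, seq, aid, animals[aid].gen, kind, payload))
        seq += 1

    def schedule(aid: str, t: int) -> None:
        a = animals[aid]
        nxt = _sample_next(cfg, rng, t, a.antenna in cfg.wheel_antennas)
        if nxt is not None:
            push(nxt[0], aid, nxt[1])

    def lag() -> int:
        lo, hi = cfg.doubling_lag_ms
        return int(rng.integers(lo, hi + 1))

    for aid in ids:
        schedule(aid, 0)

    while heap:
        t, _s, aid, gen, kind, payload = heapq.heappop(heap)
        a = animals[aid]
        if gen != a.gen:
            continue
        # a bystander's return past the horizon must still record its
        # hidden spell; everything else past the horizon is dropped
        if t >= horizon and kind != _B_RETURN:
            continue

        if kind == _MOVE:
            new = int(rng.choice(NEIGHBORS[a.antenna]))
            a.close_current(min(t + lag(), horizon))
            a.open_segment(new, t)
            a.path.append((t, new))
            schedule(aid, t)

        elif kind == _BOUT:
            if a.antenna not in cfg.wheel_antennas or a.mode != _ANT:
                schedule(aid, t)
                continue
            dur = int(round(
                1000 * min(
                    cfg.bout_duration_max_s,
                    cfg.bout_duration_median_s
                    * float(np.exp(rng.normal(0.0, cfg.bout_duration_sigma))),
                )
            ))
            dur = max(dur, 1000)
            speed = float(
                np.clip(rng.normal(cfg.bout_speed_mean_rpm, cfg.bout_speed_sd_rpm),
                        5.0, None)
            )
            right = bool(rng.random() < 0.5)
            a.close_current(t)  # vanishing into the wheel logs the OUT now
            a.mode = _WHEEL
            a.gen += 1
            a.path.append((t, 0))
            end = t + dur
            # the observable spell starts once every lagged exit has expired
            obs = min(a.vanish_time(t), end)
            a.wheel_periods.append((obs, min(end, horizon), True))
            bouts.append(Bout(aid, t, dur, speed, right))
            if end < horizon:
                push(end, aid, _WHEEL_END)
            # possibly drag a bystander under the wheel for this bout
            if rng.random() < cfg.p_bystander:
                others = [
                    o for o in ids
                    if o != aid and animals[o].mode == _ANT
                ]
                if others:
                    b = animals[others[int(rng.integers(len(others)))]]
                    d1 = int(rng.integers(500, 3001))
                    d2 = int(rng.integers(1000, 8001))
                    d1 = min(d1, max(1, dur // 5))
                    d2 = min(d2, max(1, dur // 5))
                    w = int(rng.choice(sorted(cfg.wheel_antennas)))
                    b.mode = _SCRIPT
                    b.gen += 1
                    push(t + d1, b.aid, _B_ARRIVE, (w,))
                    push(t + d1 + d2, b.aid, _B_HIDE, ())
                    push(end + int(rng.integers(200, 1001)), b.aid,
                         _B_RETURN, (w,))

        elif kind == _WHEEL_END:
            w = int(rng.choice(sorted(cfg.wheel_antennas)))
            a.mode = _ANT
            a.open_segment(w, t)
            a.path.append((t, w))
            schedule(aid, t)

        elif kind == _B_ARRIVE:
            (w,) = payload
            if a.antenna != w:
                a.close_current(min(t + lag(), horizon))
                a.open_segment(w, t)
                a.path.append((t, w))

        elif kind == _B_HIDE:
            a.close_current(t)
            a.path.append((t, 0))
            a.hide_start = a.vanish_time(t)

        elif kind == _B_RETURN:
            (w,) = payload
            a.wheel_periods.append((a.hide_start, min(t, horizon), False))
            if t < horizon:
                a.mode = _ANT
                a.open_segment(w, t)
                a.path.append((t, w))
                schedule(aid, t)

    for a in animals.values():
        a.finish(horizon)

    truth = GroundTruth(
        config=cfg,
        segments={aid: animals[aid].segments for aid in ids},
        wheel_periods={aid: animals[aid].wheel_periods for aid in ids},
        bouts=bouts,
        path={aid: animals[aid].path for aid in ids},
    )

    # artifact rotation minutes (husbandry etc.), one coin per minute
    if cfg.p_artifact_minute > 0:
        coins = rng.random(cfg.n_minutes)
        for k in np.flatnonzero(coins < cfg.p_artifact_minute):
            truth.artifact_minutes[int(k)] = int(
                rng.integers(1, cfg.artifact_rot_max + 1)
            )

    events = emit_events(truth)
    ve = emit_ve(truth, rng)
    return SimResult(events=events, ve=ve, truth=truth)


def emit_events(truth: GroundTruth) -> list[AntennaEvent]:
    """Regenerate the SCA event stream from ground-truth segments.

    This is the (pure) emitter the simulator itself uses, so replaying the
    recorded truth always reproduces the stream exactly.
    """
    cfg = truth.config
    rows: list[tuple[int, int, str, int, Optional[int]]] = []
    for aid in sorted(truth.segments):
        for antenna, t_in, t_out in truth.segments[aid]:
            rows.append((t_in, 0, aid, antenna, None))
            if t_out is not None:
                rows.append((t_out, 1, aid, antenna, t_out - t_in))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    out = []
    for t, is_out, aid, antenna, dwell in rows:
        out.append(
            AntennaEvent(
                timestamp=cfg.start + timedelta(milliseconds=t),
                cage_id=cfg.cage_id,
                animal_id=aid,
                antenna=antenna,
                direction=Direction.OUT if is_out else Direction.IN,
                dwell_ms=dwell,
            )
        )
    return out


def rotations_by_minute(start_ms: int, dur_ms: int, speed_rpm: float,
                        n_minutes: int) -> dict[int, tuple[float, int]]:
    """Split one bout into per-minute (overlap_s, rotations) contributions."""
    out: dict[int, tuple[float, int]] = {}
    end_ms = min(start_ms + dur_ms, n_minutes * MS_PER_MIN)
    k = start_ms // MS_PER_MIN
    while k * MS_PER_MIN < end_ms:
        m0, m1 = k * MS_PER_MIN, (k + 1) * MS_PER_MIN
        ov_ms = min(end_ms, m1) - max(start_ms, m0)
        if ov_ms > 0:
            ov_s = ov_ms / 1000.0
            rot = int(np.floor(speed_rpm * ov_s / 60.0 + 0.5))
            out[k] = (ov_s, rot)
        k += 1
    return out


def emit_ve(truth: GroundTruth, rng: np.random.Generator) -> list[WheelMinuteRecord]:
    """Bin bouts (plus injected artifacts) into per-minute wheel records."""
    cfg = truth.config
    n = cfg.n_minutes
    # per minute: list of (overlap_s, rot, speed, right)
    per_min: dict[int, list[tuple[float, int, float, bool]]] = {}
    for b in truth.bouts:
        for k, (ov_s, rot) in rotations_by_minute(
            b.start_ms, b.dur_ms, b.speed_rpm, n
        ).items():
            per_min.setdefault(k, []).append((ov_s, rot, b.speed_rpm, b.right))
    for k, rot in truth.artifact_minutes.items():
        ov_s = round(float(rng.uniform(2.0, 15.0)), 3)
        right = bool(rng.random() < 0.5)
        per_min.setdefault(k, []).append((ov_s, rot, 60.0 * rot / ov_s, right))

    records = []
    for k in range(n):
        contribs = per_min.get(k, [])
        rot_r = sum(rot for _o, rot, _s, right in contribs if right)
        rot_l = sum(rot for _o, rot, _s, right in contribs if not right)
        active = min(60.0, sum(o for o, *_ in contribs))
        if contribs and rot_r + rot_l > 0:
            avg = 60.0 * (rot_r + rot_l) / active if active > 0 else 0.0
            mx = max(s for _o, _r, s, _d in contribs)
            mxlen = max(o for o, *_ in contribs)
        else:
            avg = mx = mxlen = 0.0
        records.append(
            WheelMinuteRecord(
                minute_start=cfg.start + timedelta(minutes=k),
                rot_right=rot_r,
                rot_left=rot_l,
                rot_total=rot_r + rot_l,
                active_seconds=round(active, 3),
                run_count=len(contribs) if rot_r + rot_l > 0 else 0,
                max_speed_rpm=round(mx, 3),
                avg_speed_rpm=round(avg, 3),
                max_run_len_s=round(mxlen, 3),
            )
        )
    return records


# -- the three narrative wheel scenarios -------------------------------------


def make_scenario(
    name: str,
) -> tuple[list[AntennaEvent], list[WheelMinuteRecord], AssignmentResult]:
    """Hand-built single-minute fixtures for the three canonical situations.

    ``"A"``: one animal enters the wheel from antenna 2 while its cage mates
    sit elsewhere -> rotations credited to it.  ``"B"``: same, but a cage
    mate rests (detected) on wheel antenna 1 throughout -> still credited to
    the exerciser only.  ``"C"``: two animals sit detected on the wheel
    antennas and spin the wheel from outside -> rotations discarded.
    """
    if name not in {"A", "B", "C"}:
        raise ValueError(f"unknown scenario {name!r}; expected A, B or C")
    day = datetime(2022, 3, 1)

    def ev(s: float, aid: str, antenna: int, d: Direction, dwell=None):
        return AntennaEvent(
            timestamp=day + timedelta(seconds=s),
            cage_id="1",
            animal_id=aid,
            antenna=antenna,
            direction=d,
            dwell_ms=dwell,
        )

    IN, OUT = Direction.IN, Direction.OUT
    minute = day + timedelta(minutes=8)
    rot = 25
    zero = dict(rot_right=0, rot_left=0, rot_total=0, active_seconds=0.0,
                run_count=0, max_speed_rpm=0.0, avg_speed_rpm=0.0,
                max_run_len_s=0.0)
    ve = [
        WheelMinuteRecord(minute_start=day + timedelta(minutes=7), **zero),
        WheelMinuteRecord(
            minute_start=minute, rot_right=rot, rot_left=0, rot_total=rot,
            active_seconds=45.0, run_count=1, max_speed_rpm=40.0,
            avg_speed_rpm=rot / 0.75, max_run_len_s=45.0,
        ),
        WheelMinuteRecord(minute_start=day + timedelta(minutes=9), **zero),
    ]

    if name == "A":
        # A rests on 4, crosses 2 and enters the wheel; B rests on 3;
        # C moves from 6 to 5
        events = [
            ev(0.000, "A", 4, IN),
            ev(0.100, "B", 3, IN),
            ev(0.200, "C", 6, IN),
            ev(300.000, "C", 5, IN),
            ev(300.250, "C", 6, OUT, 300_050),
            ev(420.000, "A", 2, IN),
            ev(420.200, "A", 4, OUT, 420_200),
            ev(450.000, "A", 2, OUT, 30_000),
        ]
        expected = AssignmentResult(minute, rot, frozenset({"A"}), Status.ASSIGNED)
    elif name == "B":
        # as A, but C rests on (and stays detected by) wheel antenna 1
        events = [
            ev(0.000, "A", 4, IN),
            ev(0.100, "B", 3, IN),
            ev(0.200, "C", 1, IN),
            ev(420.000, "A", 2, IN),
            ev(420.200, "A", 4, OUT, 420_200),
            ev(450.000, "A", 2, OUT, 30_000),
        ]
        expected = AssignmentResult(minute, rot, frozenset({"A"}), Status.ASSIGNED)
    else:
        # A and C sit detected on the wheel antennas, spinning it from
        # outside; B rests on 3; nobody qualifies
        events = [
            ev(0.000, "A", 2, IN),
            ev(0.100, "B", 3, IN),
            ev(0.200, "C", 1, IN),
        ]
        expected = AssignmentResult(
            minute, rot, frozenset(), Status.DISCARDED,
            Reason.ALL_CANDIDATES_DETECTED,
        )
    return events, ve, expected
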