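"""Summary surfaces: animal-hour tables, daily counts, circadian profiles.

These are the tables the original analysis reports: deduplicated field
changes per animal per hour (optionally combined with the credited wheel
rotations for that hour), field changes per 24 h, and the percent-per-hour
circadian profile — each clock hour's share of the day's total activity,
averaged over days.

Aggregation is strictly additive: hourly rows summed over a day equal the
daily count, because the daily count is *defined* as the sum of its hours
(windows are independent by default; ``carry_state=True`` carries the
animal's last antenna across window boundaries instead).
"""

from __future__ import annotations

import logging
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .occupancy import in_sequence, to_ms
from .types import AntennaEvent, AssignmentResult, CircadianProfile, WheelMinuteRecord

logger = logging.getLogger(__name__)

MS_PER_HOUR = 3_600_000


def _floor_hour(ts: datetime) -> datetime:
    return ts.replace(minute=0, second=0, microsecond=0)


def _hour_edges(start: datetime, end: datetime) -> np.ndarray:
    """Edges of the hour grid covering [start, end), in ms."""
    h0 = _floor_hour(start)
    n = 0
    while h0 + timedelta(hours=n) < end:
        n += 1
    return np.array(
        [to_ms(h0 + timedelta(hours=i)) for i in range(n + 1)], dtype=np.int64
    )


def _fc_per_window(
    ts: np.ndarray, ant: np.ndarray, edges: np.ndarray, carry_state: bool
) -> np.ndarray:
    """Deduplicated field changes of one animal in each window of ``edges``.

    A field change is an IN whose antenna differs from the previous IN; with
    independent windows the first IN of each window never pairs backwards.
    """
    n_win = len(edges) - 1
    counts = np.zeros(n_win, dtype=np.int64)
    if ts.size == 0:
        return counts
    changed = np.empty(ts.size, dtype=bool)
    changed[0] = False
    changed[1:] = ant[1:] != ant[:-1]
    win = np.searchsorted(edges, ts, side="right") - 1
    inside = (win >= 0) & (win < n_win)
    if not carry_state:
        # zero the flag of each window's first IN
        first = np.ones(ts.size, dtype=bool)
        first[1:] = win[1:] != win[:-1]
        changed = changed & ~first
    sel = inside & changed
    np.add.at(counts, win[sel], 1)
    return counts


def hourly_table(
    events: Sequence[AntennaEvent],
    assignments: Sequence[AssignmentResult] = (),
    animals: Optional[Sequence[str]] = None,
    time_range: Optional[tuple[datetime, datetime]] = None,
    ve_records: Sequence[WheelMinuteRecord] = (),
    carry_state: bool = False,
) -> pd.DataFrame:
    """One row per (animal, hour), zero-filled over the covered range.

    Columns: ``animal_id, hour_start, field_changes, rotations_credited,
    wheel_active_seconds``.  Rotations come from the assignment results whose
    minute falls in the hour; wheel seconds from the matching VE minutes of
    credited results (when ``ve_records`` is supplied).
    """
    if animals is None:
        animals = sorted({e.animal_id for e in events})
    if time_range is None:
        if not events:
            raise ValueError("no events and no explicit time range")
        time_range = (
            events[0].timestamp,
            events[-1].timestamp + timedelta(milliseconds=1),
        )
    edges = _hour_edges(*time_range)
    hours = [pd.Timestamp(edges[i] * 10**6).to_pydatetime()
             for i in range(len(edges) - 1)]

    active_s = {to_ms(r.minute_start): r.active_seconds for r in ve_records}
    rot = {a: np.zeros(len(hours), dtype=np.int64) for a in animals}
    wheel_s = {a: np.zeros(len(hours)) for a in animals}
    for res in assignments:
        m = to_ms(res.minute_start)
        h = int(np.searchsorted(edges, m, side="right")) - 1
        if h < 0 or h >= len(hours):
            continue
        for a in res.credited:
            if a in rot:
                rot[a][h] += res.rot_total
                wheel_s[a][h] += active_s.get(m, 0.0)

    frames = []
    for a in animals:
        ts, ant = in_sequence(events, a)
        fc = _fc_per_window(ts, ant, edges, carry_state)
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": a,
                    "hour_start": hours,
                    "field_changes": fc,
                    "rotations_credited": rot[a],
                    "wheel_active_seconds": wheel_s[a],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _day_floor(ts: pd.Series, boundary_hour: int) -> pd.Series:
    shifted = ts - pd.Timedelta(hours=boundary_hour)
    return shifted.dt.normalize() + pd.Timedelta(hours=boundary_hour)


def daily_fc(
    events: Sequence[AntennaEvent],
    animals: Optional[Sequence[str]] = None,
    time_range: Optional[tuple[datetime, datetime]] = None,
    day_boundary_hour: int = 0,
    carry_state: bool = False,
) -> pd.DataFrame:
    """Field changes per animal per 24 h window (sum of the hourly counts).

    ``day_boundary_hour`` aligns the 24 h windows: 0 = midnight (default),
    6 = light onset.
    """
    hourly = hourly_table(
        events, animals=animals, time_range=time_range, carry_state=carry_state
    )
    hs = pd.to_datetime(hourly["hour_start"])
    hourly = hourly.assign(day_start=_day_floor(hs, day_boundary_hour))
    out = (
        hourly.groupby(["animal_id", "day_start"], as_index=False)["field_changes"]
        .sum()
    )
    return out


def circadian_profile(
    events: Sequence[AntennaEvent],
    animals: Optional[Sequence[str]] = None,
    time_range: Optional[tuple[datetime, datetime]] = None,
    day_boundary_hour: int = 0,
    carry_state: bool = False,
    combine: bool = True,
    label: str = "group",
):
    """Percent of daily field changes in each clock hour, averaged over days.

    Days with zero field changes are excluded with a warning.  With
    ``combine`` (default) one profile is built from the summed activity of
    all animals; otherwise a dict of per-animal profiles is returned.
    The 24 percentages of a profile sum to 100.
    """
    hourly = hourly_table(
        events, animals=animals, time_range=time_range, carry_state=carry_state
    )
    if not combine:
        return {
            a: _profile_from_hourly(sub, day_boundary_hour, label=a)
            for a, sub in hourly.groupby("animal_id")
        }
    summed = hourly.groupby("hour_start", as_index=False)["field_changes"].sum()
    return _profile_from_hourly(summed, day_boundary_hour, label=label)


def _profile_from_hourly(
    hourly: pd.DataFrame, day_boundary_hour: int, label: str
) -> CircadianProfile:
    df = hourly.copy()
    hs = pd.to_datetime(df["hour_start"])
    df["day_start"] = _day_floor(hs, day_boundary_hour)
    df["clock_hour"] = hs.dt.hour
    # only full days can be expressed as shares of a daily total
    full = df.groupby("day_start")["clock_hour"].transform("size") == 24
    df = df[full]
    pivot = df.pivot_table(
        index="day_start", columns="clock_hour", values="field_changes",
        aggfunc="sum", fill_value=0,
    ).reindex(columns=range(24), fill_value=0)
    totals = pivot.sum(axis=1)
    dead = totals == 0
    if dead.any():
        logger.warning(
            "excluding %d day(s) with zero field changes from the profile",
            int(dead.sum()),
        )
        pivot = pivot[~dead]
        totals = totals[~dead]
    if pivot.empty:
        return CircadianProfile(label=label, percent_by_hour=(0.0,) * 24,
                                n_days=0, per_day=pivot)
    per_day = pivot.div(totals, axis=0) * 100.0
    mean = per_day.mean(axis=0)
    return CircadianProfile(
        label=label,
        percent_by_hour=tuple(float(mean[h]) for h in range(24)),
        n_days=len(per_day),
        per_day=per_day,
    )


def dark_light_ratio(
    profile: CircadianProfile, light_on_hour: int = 6, light_off_hour: int = 18
) -> float:
    """Ratio of mean dark-hour share to mean light-hour share."""
    light = [
        p for h, p in enumerate(profile.percent_by_hour)
        if light_on_hour <= h < light_off_hour
    ]
    dark = [
        p for h, p in enumerate(profile.percent_by_hour)
        if not light_on_hour <= h < light_off_hour
    ]
    light_mean = float(np.mean(light))
    if light_mean == 0:
        return float("inf")
    return float(np.mean(dark)) / light_mean


def group_mean_sem(values_by_animal: dict[str, float]) -> tuple[float, float]:
    """Mean +/- SEM over animals (the group summary convention)."""
    vals = np.asarray(list(values_by_animal.values()), dtype=float)
    if vals.size == 0:
        return float("nan"), float("nan")
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return float(vals.mean()), sem


def anova_oneway(groups: dict[str, Sequence[float]]) -> tuple[float, float]:
    """Convenience one-way ANOVA across groups of per-animal values."""
    f, p = stats.f_oneway(*[np.asarray(v, dtype=float) for v in groups.values()])
    return float(f), float(p)
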