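"""Core record types shared across the package.

The two instrument streams are modelled as flat, immutable records:
:class:`AntennaEvent` rows come from the RFID floor-grid log (one row per
change of detection state), :class:`WheelMinuteRecord` rows from the running
wheel's per-minute export.  Everything downstream (occupancy intervals,
assignment results, hourly summaries) is derived from these.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

ANTENNA_LABELS = frozenset(range(1, 7))


class Direction(str, enum.Enum):
    """Whether a logged row marks entry into or exit from an antenna field."""

    IN = "IN"
    OUT = "OUT"


class Status(str, enum.Enum):
    """Outcome of assigning one wheel-active minute."""

    ASSIGNED = "ASSIGNED"
    ASSIGNED_MULTI = "ASSIGNED_MULTI"
    DISCARDED = "DISCARDED"


class Reason(str, enum.Enum):
    """Why a wheel-active minute was (or was not) discarded."""

    NONE = "NONE"
    #: no animal ever touched a wheel antenna in a qualifying way
    NO_CANDIDATE = "NO_CANDIDATE"
    #: animals were on the wheel antennas but stayed detected the whole time
    ALL_CANDIDATES_DETECTED = "ALL_CANDIDATES_DETECTED"


@dataclass(frozen=True, slots=True)
class AntennaEvent:
    """One detection-change row of the RFID platform log.

    ``dwell_ms`` (the instrument's "MS" column, time spent on the antenna)
    is only meaningful on OUT rows and is ``None`` on IN rows.
    """

    timestamp: datetime
    cage_id: str
    animal_id: str
    antenna: int
    direction: Direction
    dwell_ms: Optional[int] = None

    def __post_init__(self) -> None:
        if self.antenna not in ANTENNA_LABELS:
            raise ValueError(f"antenna must be in 1..6, got {self.antenna}")
        if self.dwell_ms is not None and self.dwell_ms < 0:
            raise ValueError(f"dwell_ms must be >= 0, got {self.dwell_ms}")


@dataclass(frozen=True, slots=True)
class WheelMinuteRecord:
    """One per-minute row of the running-wheel export.

    Rotations are split by direction; ``rot_total`` must equal their sum.
    ``active_seconds`` is the portion of the minute the wheel was moving.
    """

    minute_start: datetime
    rot_right: int
    rot_left: int
    rot_total: int
    active_seconds: float
    run_count: int
    max_speed_rpm: float
    avg_speed_rpm: float
    max_run_len_s: float

    def __post_init__(self) -> None:
        if self.rot_total != self.rot_right + self.rot_left:
            raise ValueError(
                f"rot_total={self.rot_total} != rot_right+rot_left="
                f"{self.rot_right + self.rot_left}"
            )
        if min(self.rot_right, self.rot_left, self.run_count) < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.active_seconds <= 60:
            raise ValueError(
                f"active_seconds must lie in [0, 60], got {self.active_seconds}"
            )

    @property
    def is_active(self) -> bool:
        return self.rot_total > 0


@dataclass(frozen=True, slots=True)
class OccupancyInterval:
    """Presence of one animal on one antenna, half-open ``[start, end)``.

    ``end is None`` marks an interval still open at the end of the stream
    (no OUT logged: the animal is either resting there or left detection
    range without a logged exit).
    """

    animal_id: str
    antenna: int
    start: datetime
    end: Optional[datetime] = None

    def __post_init__(self) -> None:
        if self.end is not None and self.end < self.start:
            raise ValueError("interval end precedes start")

    @property
    def is_open(self) -> bool:
        return self.end is None


@dataclass(frozen=True, slots=True)
class DetectionState:
    """Snapshot of one animal's detectability at a single instant."""

    animal_id: str
    at: datetime
    detected: bool
    last_closed_antenna: Optional[int] = None


@dataclass(frozen=True)
class AssignmentResult:
    """Attribution outcome for one wheel-active minute."""

    minute_start: datetime
    rot_total: int
    credited: frozenset[str]
    status: Status
    reason: Reason = Reason.NONE

    def __post_init__(self) -> None:
        n = len(self.credited)
        if self.status is Status.DISCARDED and n:
            raise ValueError("discarded minute must credit no animal")
        if self.status is Status.ASSIGNED and n != 1:
            raise ValueError("ASSIGNED requires exactly one credited animal")
        if self.status is Status.ASSIGNED_MULTI and n < 2:
            raise ValueError("ASSIGNED_MULTI requires >= 2 credited animals")


@dataclass(frozen=True)
class WheelConfig:
    """Parameters of the assignment rule.

    wheel_antennas
        Antenna fields the wheel stands on (the instrument requires 1 and 2).
    strictness
        ``"whole-minute"``: the qualifying animal must be undetected for the
        entire rotation minute.  A float ``f`` in ``[0, 1]`` allows the animal
        to be detected for at most fraction ``f`` of the minute (it must still
        have some undetected gap whose last-closed antenna is a wheel
        antenna); ``1.0`` reduces the rule to "any undetected gap entered
        from a wheel antenna".
    max_gap_s
        If set, the exit (OUT) from the wheel antenna must fall within this
        many seconds before the rotation minute starts.  ``None`` = no bound.
    roster
        Explicit animal roster; ``None`` infers it from the event stream.
    """

    wheel_antennas: frozenset[int] = frozenset({1, 2})
    strictness: "str | float" = "whole-minute"
    max_gap_s: Optional[float] = None
    roster: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if not self.wheel_antennas or not self.wheel_antennas <= ANTENNA_LABELS:
            raise ValueError("wheel_antennas must be a non-empty subset of 1..6")
        f = self.detected_fraction_max
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"strictness fraction must lie in [0, 1], got {f}")

    @property
    def detected_fraction_max(self) -> float:
        """Maximum tolerated detected fraction of the rotation minute."""
        if self.strictness == "whole-minute":
            return 0.0
        return float(self.strictness)


@dataclass(frozen=True, slots=True)
class HourlySummary:
    """Per-animal, per-hour activity row (zero-filled over the range)."""

    animal_id: str
    hour_start: datetime
    field_changes: int
    rotations_credited: int = 0
    wheel_active_seconds: float = 0.0


@dataclass(frozen=True)
class CircadianProfile:
    """Percent of daily field changes falling in each clock hour.

    ``percent_by_hour[h]`` is that clock-hour's share of the day's total,
    averaged over all days with at least one field change; the 24 values sum
    to 100 for any animal or group with activity.
    """

    label: str
    percent_by_hour: tuple[float, ...]
    n_days: int = 0
    per_day: "object" = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.percent_by_hour) != 24:
            raise ValueError("percent_by_hour must have 24 entries")
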