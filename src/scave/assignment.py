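"""Attribution of wheel-active minutes to individual animals.

The wheel has no RFID antenna of its own, so rotations are credited by
elimination: the wheel stands on known antenna fields (1 and 2 by default),
and an animal inside it is invisible to the whole platform.  A minute's
rotations are credited to every animal that

(a) last closed an occupancy interval on a wheel antenna before going
    undetected — it entered the wheel zone and vanished there — and
(b) was not detected during the rotation interval (whole-minute strictness),
    or was detected for at most a configured fraction of it.

If two animals satisfy both premises the full count is credited to each
(simultaneous exercise); if none does, the minute is discarded — this is
what filters out rotations caused by husbandry (cage cleaning, weighing) or
by animals spinning the wheel from the outside while remaining detected.
"""

from __future__ import annotations

import logging
from datetime import datetime, timedelta
from typing import Optional, Sequence

from .occupancy import Occupancy, build_occupancy, from_ms, to_ms
from .types import (
    AntennaEvent,
    AssignmentResult,
    Reason,
    Status,
    WheelConfig,
    WheelMinuteRecord,
)

logger = logging.getLogger(__name__)

MINUTE = timedelta(minutes=1)


def _qualifies(
    occ: Occupancy,
    animal_id: str,
    start: datetime,
    end: datetime,
    config: WheelConfig,
) -> bool:
    """Does this animal satisfy both premises over [start, end)?"""
    span_ms = to_ms(end) - to_ms(start)
    detected = occ.detected_ms(animal_id, start, end)
    if detected > config.detected_fraction_max * span_ms:
        return False
    gap_ms = occ.first_gap_start(animal_id, start, end)
    if gap_ms is None:  # detected throughout (only reachable when f == 1)
        return False
    # premise (a) asks which field the animal *entered* last before
    # vanishing; selecting by latest start keeps the answer right when a
    # doubling-lagged exit of the previous antenna registers after the
    # wheel-entry exit
    last = occ.last_entered(animal_id, from_ms(gap_ms))
    if last is None or last[0] not in config.wheel_antennas:
        return False
    if config.max_gap_s is not None:
        if to_ms(start) - last[1] > config.max_gap_s * 1000:
            return False
    return True


def _near_wheel(
    occ: Occupancy, animal_id: str, start: datetime, end: datetime,
    config: WheelConfig,
) -> bool:
    """Premise (a) alone: the animal's trace touches a wheel antenna —
    either its latest closed interval is on one, or it is detected on one
    during the rotation interval.  Used to pick the discard reason."""
    last = occ.last_closed(animal_id, end)
    if last is not None and last[0] in config.wheel_antennas:
        return True
    t0, t1 = to_ms(start), to_ms(end)
    for iv in occ.intervals(animal_id):
        if iv.antenna not in config.wheel_antennas:
            continue
        s = to_ms(iv.start)
        e = t1 if iv.is_open else to_ms(iv.end)
        if s < t1 and e > t0:
            return True
    return False


def candidates(
    occ: Occupancy,
    animals: Sequence[str],
    start: datetime,
    end: datetime,
    config: WheelConfig = WheelConfig(),
) -> set[str]:
    """Animals qualifying for the rotation interval [start, end)."""
    return {a for a in animals if _qualifies(occ, a, start, end, config)}


def assign_ve(
    events: Sequence[AntennaEvent],
    ve_records: Sequence[WheelMinuteRecord],
    config: WheelConfig = WheelConfig(),
    occ: Optional[Occupancy] = None,
) -> list[AssignmentResult]:
    """Attribute every wheel-active minute; inactive minutes yield no result.

    The animal roster is the set of RFIDs seen in the event stream unless
    ``config.roster`` pins it explicitly (so a failed chip is noticed rather
    than silently shrinking the roster).
    """
    if occ is None:
        occ = build_occupancy(events)
    if config.roster is not None:
        roster = list(config.roster)
        missing = set(roster) - set(occ.animals)
        if missing:
            logger.warning(
                "roster animal(s) never seen in the event stream: %s",
                ", ".join(sorted(missing)),
            )
    else:
        roster = occ.animals
    first_seen = events[0].timestamp if events else None

    results: list[AssignmentResult] = []
    for rec in ve_records:
        if rec.rot_total <= 0:
            continue
        m0 = rec.minute_start
        m1 = m0 + MINUTE
        # a quiet cage emits no events, so only minutes before tracking
        # started are genuinely uncovered
        if first_seen is None or m1 <= first_seen:
            logger.warning(
                "wheel-active minute %s outside tracking coverage", m0
            )
        cred = candidates(occ, roster, m0, m1, config)
        if not cred:
            reason = (
                Reason.ALL_CANDIDATES_DETECTED
                if any(_near_wheel(occ, a, m0, m1, config) for a in roster)
                else Reason.NO_CANDIDATE
            )
            results.append(
                AssignmentResult(m0, rec.rot_total, frozenset(), Status.DISCARDED, reason)
            )
        else:
            status = Status.ASSIGNED if len(cred) == 1 else Status.ASSIGNED_MULTI
            results.append(
                AssignmentResult(m0, rec.rot_total, frozenset(cred), status)
            )
    _check_conservation(ve_records, results)
    return results


def _check_conservation(ve_records, results) -> None:
    """Every measured rotation is either credited (k times for k candidates)
    or discarded — asserted on every run."""
    measured = sum(r.rot_total for r in ve_records if r.rot_total > 0)
    accounted = sum(r.rot_total for r in results)
    if measured != accounted:
        raise AssertionError(
            f"rotation conservation violated: measured {measured}, "
            f"accounted {accounted}"
        )


def credited_rotations(results: Sequence[AssignmentResult]) -> dict[str, int]:
    """Total rotations credited to each animal (full count per candidate)."""
    totals: dict[str, int] = {}
    for r in results:
        for a in r.credited:
            totals[a] = totals.get(a, 0) + r.rot_total
    return totals


def discard_report(results: Sequence[AssignmentResult]) -> dict[str, dict[str, int]]:
    """Discarded minutes and rotations, split by reason code."""
    report = {
        reason.value: {"minutes": 0, "rotations": 0}
        for reason in (Reason.NO_CANDIDATE, Reason.ALL_CANDIDATES_DETECTED)
    }
    for r in results:
        if r.status is Status.DISCARDED:
            entry = report[r.reason.value]
            entry["minutes"] += 1
            entry["rotations"] += r.rot_total
    report["TOTAL"] = {
        "minutes": sum(v["minutes"] for v in report.values()),
        "rotations": sum(v["rotations"] for v in report.values()),
    }
    return report
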