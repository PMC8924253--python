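"""Interval reconstruction from the change-log event stream."""

import numpy as np
import pytest

from scave.occupancy import (
    AnomalousEventError,
    build_occupancy,
    detection_state,
    to_ms,
)
from scave.types import AntennaEvent, Direction

from .util import (
    EPOCH,
    brute_force_detected,
    brute_force_on_antenna,
    ms_to_dt,
    random_legal_stream,
)


def ev(ms, animal, antenna, direction, dwell=None):
    return AntennaEvent(
        timestamp=ms_to_dt(ms),
        cage_id="1",
        animal_id=animal,
        antenna=antenna,
        direction=Direction[direction],
        dwell_ms=dwell,
    )


def test_simple_pair_closes_interval():
    occ = build_occupancy([ev(0, "A", 1, "IN"), ev(5000, "A", 1, "OUT", 5000)])
    (iv,) = occ.intervals("A")
    assert (iv.antenna, iv.start, iv.end) == (1, ms_to_dt(0), ms_to_dt(5000))


def test_doubling_overlap_is_retained():
    """Entering the next antenna before leaving the previous one yields two
    overlapping intervals, not an error."""
    occ = build_occupancy(
        [
            ev(0, "A", 1, "IN"),
            ev(3000, "A", 2, "IN"),
            ev(4000, "A", 1, "OUT", 4000),
            ev(9000, "A", 2, "OUT", 6000),
        ]
    )
    ivs = occ.intervals("A")
    assert [(iv.antenna, iv.start, iv.end) for iv in ivs] == [
        (1, ms_to_dt(0), ms_to_dt(4000)),
        (2, ms_to_dt(3000), ms_to_dt(9000)),
    ]
    # both open on the overlap
    assert occ.is_detected("A", ms_to_dt(3500))
    assert occ.detected_ms("A", ms_to_dt(0), ms_to_dt(9000)) == 9000


def test_unmatched_in_stays_open():
    occ = build_occupancy([ev(0, "A", 3, "IN")])
    (iv,) = occ.intervals("A")
    assert iv.is_open
    assert occ.is_detected("A", ms_to_dt(10**9))


def test_orphan_out_skipped_or_strict_error(caplog):
    events = [ev(0, "A", 1, "IN"), ev(100, "A", 2, "OUT", 50)]
    with caplog.at_level("WARNING"):
        occ = build_occupancy(events)
    assert "no open interval" in caplog.text
    assert len(occ.intervals("A")) == 1
    with pytest.raises(AnomalousEventError):
        build_occupancy(events, strict=True)


def test_repeated_in_ignored(caplog):
    with caplog.at_level("WARNING"):
        occ = build_occupancy(
            [ev(0, "A", 1, "IN"), ev(50, "A", 1, "IN"), ev(900, "A", 1, "OUT", 900)]
        )
    assert "repeated IN" in caplog.text
    (iv,) = occ.intervals("A")
    assert iv.start == ms_to_dt(0) and iv.end == ms_to_dt(900)


def test_decreasing_timestamps_rejected():
    with pytest.raises(AnomalousEventError, match="time-ordered"):
        build_occupancy([ev(100, "A", 1, "IN"), ev(0, "A", 1, "OUT", 0)])


@pytest.mark.parametrize("seed", range(8))
def test_intervals_match_per_millisecond_replay(seed):
    """Flattened occupancy equals the brute-force replay of the stream."""
    rng = np.random.default_rng(seed)
    span = 3000
    events = random_legal_stream(rng, n_events=300, span_ms=span)
    occ = build_occupancy(events)

    expected = brute_force_on_antenna(events, span)
    got = {k: np.zeros(span, dtype=bool) for k in expected}
    for animal, ivs in occ.by_animal.items():
        for iv in ivs:
            s = to_ms(iv.start) - to_ms(EPOCH)
            e = span if iv.is_open else to_ms(iv.end) - to_ms(EPOCH)
            got[(animal, iv.antenna)][s:e] = True
    assert set(got) == set(expected)
    for k in expected:
        np.testing.assert_array_equal(got[k], expected[k], err_msg=str(k))

    detected = brute_force_detected(events, span)
    for animal, arr in detected.items():
        for t in range(0, span, 7):
            assert occ.is_detected(animal, ms_to_dt(t)) == arr[t]


def test_detection_state_examples():
    events = [
        ev(0, "A", 4, "IN"),
        ev(60_000, "A", 2, "IN"),
        ev(60_200, "A", 4, "OUT", 60_200),
        ev(90_000, "A", 2, "OUT", 30_000),  # A enters the wheel
        ev(0, "C", 1, "IN"),  # C rests on antenna 1
    ]
    events.sort(key=lambda e: e.timestamp)
    occ = build_occupancy(events)

    resting = detection_state(occ, "C", ms_to_dt(120_000))
    assert resting.detected and resting.last_closed_antenna is None

    in_wheel = detection_state(occ, "A", ms_to_dt(120_000))
    assert not in_wheel.detected
    assert in_wheel.last_closed_antenna == 2

    before = detection_state(occ, "A", ms_to_dt(-1))
    assert not before.detected and before.last_closed_antenna is None


def test_last_entered_differs_under_lagged_exit():
    """When the previous antenna's OUT registers after the wheel-entry OUT,
    the latest *end* names the stale field but the latest *start* names the
    field the animal actually vanished from."""
    events = [
        ev(0, "A", 5, "IN"),
        ev(10_000, "A", 2, "IN"),  # crossed onto the wheel antenna
        ev(10_050, "A", 2, "OUT", 50),  # straight into the wheel
        ev(10_300, "A", 5, "OUT", 10_300),  # lagged exit of antenna 5
    ]
    occ = build_occupancy(events)
    at = ms_to_dt(20_000)
    assert occ.last_closed("A", at)[0] == 5
    assert occ.last_entered("A", at)[0] == 2


def test_first_gap_and_detected_fraction():
    events = [
        ev(0, "A", 1, "IN"),
        ev(10_000, "A", 1, "OUT", 10_000),
        ev(40_000, "A", 2, "IN"),
    ]
    occ = build_occupancy(events)
    w0, w1 = ms_to_dt(0), ms_to_dt(60_000)
    assert occ.first_gap_start("A", w0, w1) == to_ms(ms_to_dt(10_000))
    assert occ.detected_ms("A", w0, w1) == 10_000 + 20_000
    # fully covered window has no gap
    assert occ.first_gap_start("A", ms_to_dt(0), ms_to_dt(10_000)) is None
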