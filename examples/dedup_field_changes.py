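"""Deduplicated field changes: why OUT rows must not be counted.

An animal entering the next antenna field before the previous field logs
its exit ("doubling") makes naive row counting overshoot.  Counting only
IN rows with a changed antenna label removes the artefact.
"""

from datetime import datetime, timedelta

from scave import AntennaEvent, Direction, field_changes

t0 = datetime(2022, 3, 1)


def ev(seconds, antenna, direction, dwell=None):
    return AntennaEvent(
        timestamp=t0 + timedelta(seconds=seconds),
        cage_id="1", animal_id="A", antenna=antenna,
        direction=Direction[direction], dwell_ms=dwell,
    )


# the animal walks 4 -> 2 -> 1; each exit registers a moment *after* the
# next entry, so the raw log interleaves INs and OUTs
events = [
    ev(0.0, 4, "IN"),
    ev(10.0, 2, "IN"),
    ev(10.3, 4, "OUT", 10_300),
    ev(20.0, 1, "IN"),
    ev(20.2, 2, "OUT", 10_200),
]

naive_rows = sum(
    1 for a, b in zip(events, events[1:]) if a.antenna != b.antenna
)
dedup = field_changes(events, "A")

print(f"raw rows:                  {len(events)}")
print(f"naive row-to-row changes:  {naive_rows}")
print(f"deduplicated field changes: {dedup}")
# The animal crossed two field borders; the naive count sees four because
# every lagged OUT row flips the antenna column once more.
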