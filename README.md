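# scave

Individual attribution of voluntary wheel running and deduplicated
spontaneous cage activity for **group-housed, RFID-tracked rodents**.

## The problem

Wheel-running studies usually single-house rodents because a cage-level
rotation counter cannot tell which animal is running — but social isolation
is itself a stressor that changes activity and exercise behaviour.  A way
around this combines two instruments under one cage:

* an RFID floor platform whose cage area spans a 2×3 grid of antenna
  fields (labels 1–6), logging one row per *change* of detection state —
  which animal entered (`IN`) or left (`OUT`) which field, with
  millisecond timestamps and dwell time;
* a running wheel standing on fields 1 and 2, logging per-minute rotation
  counts (left/right), active seconds, run counts and speeds — for the
  whole cage, with no identity information.

Two observations make individual attribution possible:

1. an animal inside the wheel is **invisible to every antenna** (distance
   and wheel material), so entering the wheel logs an `OUT` on a wheel
   field and nothing afterwards;
2. the wheel's location is known, so the animal that vanished must have
   last entered field 1 or 2.

A wheel-active minute is therefore credited to every animal that
**(a)** last entered a wheel field before going undetected and
**(b)** was not detected while the wheel turned.  If two animals qualify
(simultaneous exercise) each is credited the full count; if none does —
outside spinning, husbandry artifacts — the minute is discarded.

Spontaneous cage activity (SCA) is quantified as **field changes**:
transitions between antenna fields, counted on `IN` rows only.  Counting
raw rows overshoots, because an animal registers on the next field slightly
*before* the previous field logs its exit ("doubling"); consecutive `IN`
rows with differing labels count exactly one change each, which removes the
artifact.

## What the package provides

| module | role |
| --- | --- |
| `scave.io` | readers/writers for the two instrument CSV dialects (`intl`/`de`, auto-detected) and result tables |
| `scave.occupancy` | per-animal occupancy intervals from the IN/OUT change log; detection queries; deduplicated field changes |
| `scave.assignment` | the attribution rule: candidates, per-minute crediting, discard reporting, conservation checks |
| `scave.aggregate` | animal-hour tables, field changes per 24 h, percent-per-hour circadian profiles, group mean ± SEM |
| `scave.simulate` | seeded cage simulator (continuous-time Markov walk, wheel bouts, bystander and artifact confounds) with complete ground truth |
| `scave.cli` | `scave simulate / assign / sca-summary / profile` |

No public recordings of these instrument streams exist, so the simulator is
first-class: it reproduces the detection semantics the rule relies on and
provides the ground truth every other module is tested against.

## Worked example

```python
from scave import SimConfig, WheelConfig, simulate_cage, assign_ve, \
    credited_rotations, make_scenario

# the three canonical situations
for name in "ABC":
    events, ve, _ = make_scenario(name)
    (result,) = assign_ve(events, ve)
    print(name, result.status.value, sorted(result.credited), result.reason.value)
```

```
A ASSIGNED ['A'] NONE
B ASSIGNED ['A'] NONE
C DISCARDED [] ALL_CANDIDATES_DETECTED
```

Scenario A: animal A rests on field 4, crosses field 2 and vanishes into
the wheel while B and C sit detected elsewhere — the 25 rotations go to A.
Scenario B: the same, but C rests *detected* on wheel field 1 the whole
minute — C fails premise (b) and A is still the sole candidate.  Scenario
C: A and C sit detected on fields 2 and 1 and spin the wheel from outside —
nobody qualifies and the minute is discarded.

```python
sim = simulate_cage(SimConfig(seed=7, duration_days=2.0))
results = assign_ve(sim.events, sim.ve, WheelConfig(strictness=1.0))
print(len(results), "wheel-active minutes", credited_rotations(results))
```

```
634 wheel-active minutes {'A': 7295, 'C': 4725, 'B': 7005, 'D': 6870}
```

Each credited total is that animal's attributed wheel rotations over the
two simulated days; the per-minute results carry the status
(`ASSIGNED`/`ASSIGNED_MULTI`/`DISCARDED`) and a discard reason code.
`examples/` contains one narrative script per capability.

From a shell:

```bash
scave simulate --seed 7 --days 2 -o out/
scave assign --sca out/sca.csv --ve out/ve.csv --strictness 1.0 -o out/assign.csv
scave sca-summary --sca out/sca.csv --ve out/ve.csv -o out/hourly.csv
scave profile --sca out/sca.csv -o out/profile.csv
```

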