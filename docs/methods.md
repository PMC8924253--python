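# Methods

## Setting and data model

A standard cage sits on an RFID platform whose cage area spans a 2×3 grid
of equally sized antenna fields, labelled

```
1 2 3
4 5 6
```

with a running wheel standing on fields 1 and 2.  Each animal carries a
subcutaneous RFID chip.  The platform samples several times a second but
logs only *changes* of detection state: one row per field entry (`IN`) or
exit (`OUT`), with a millisecond timestamp and, on `OUT` rows, the dwell
time on that field (`MS`).  The wheel logs per-minute aggregates: left and
right rotations, active seconds, run count and speeds, with no identity.
All timestamps are naive local clock at millisecond resolution.

## Occupancy reconstruction

Each `IN` opens a half-open interval `[start, end)` on (animal, antenna);
the matching `OUT` closes it.  An animal may enter the next field before
the previous field logs its exit — the *doubling* phenomenon — so
intervals of one animal on different fields can overlap briefly; the
overlap is retained.  An animal is **detected** at an instant iff at least
one of its intervals is open there: the log has no heartbeat, so a resting
animal (last event `IN`) counts as continuously detected until its `OUT`.
Unmatched `IN`s at the end of a stream stay open.  Anomalies (an `OUT`
without an open interval, a repeated `IN` on an open field) are logged and
skipped by default and raise in strict mode; timestamps must be
non-decreasing.

## Field changes (SCA)

Spontaneous cage activity is quantified as field changes: only `IN` rows
are considered, and each consecutive pair of `IN`s with differing antenna
labels counts one change.  `OUT` rows and repeated `IN`s on the same field
contribute nothing, which removes the doubled counts that naive
row-difference counting produces.  Windows `[t_a, t_b)` are independent by
default (the first `IN` in a window pairs with nothing before it);
`carry_state=True` carries the animal's last antenna across the boundary
instead, which makes per-window counts sum exactly to the number of
crossings and is what the rate-recovery analyses use.

## Attribution of wheel minutes (VE)

For every minute with a positive rotation count, an animal qualifies iff

* **(a)** the most recently *entered* field among its intervals closed by
  its first undetected instant is a wheel field, and
* **(b)** it satisfies the detection-strictness bound over the rotation
  interval (the full minute, since the wheel data are per-minute).

Strictness is configurable because the instrument aggregates per minute
while premise (b) conceptually applies only "while the wheel rotates":

* `"whole-minute"` (default): the animal must be undetected for the whole
  minute.  Conservative; necessarily discards the boundary minutes of a
  bout that starts or ends mid-minute, because the exerciser is still
  detected for part of those minutes.
* a float `f ∈ [0, 1]`: the animal may be detected for at most fraction
  `f` of the minute but must still have an undetected gap entered from a
  wheel field.  `f = 1.0` reduces the rule to "any undetected gap entered
  from a wheel field" and recovers bout-boundary minutes exactly; the
  ground-truth validation runs in this mode.

Premise (a) deliberately selects the last *entered* (latest start) rather
than the last *closed* (latest end) interval: with doubling, the lagged
exit of the previous field can register after the wheel-entry exit, and
the by-end reading would then name the wrong field and discard genuine
exercise.  An optional `max_gap_s` additionally bounds the time between
the qualifying exit and the rotation minute (default unbounded — premise
(a) constrains *which* field was last, not when).

When several animals qualify, each is credited the **full** rotation
count (they may genuinely exercise simultaneously); counts are never
split.  When none qualifies the minute is discarded, with a reason code:
`ALL_CANDIDATES_DETECTED` if some animal touched a wheel field but stayed
detected (outside spinning), otherwise `NO_CANDIDATE` (e.g. husbandry
artifacts).  Conservation — every measured rotation either credited (k
times for k candidates) or discarded — is asserted on every run.

## Aggregation

The animal-hour table zero-fills every (animal, hour) of the covered
range with deduplicated field changes, credited rotations and wheel-active
seconds.  Daily counts are *defined* as the sum of the 24 hourly counts,
aligned to a configurable day boundary (midnight by default, light onset
optionally).  The circadian profile expresses each clock hour as percent
of that day's total field changes, averaged over days; days with zero
activity are excluded with a warning, and the 24 values sum to 100.
Group summaries are mean ± SEM over animals; a one-way ANOVA wrapper
(scipy) is provided as a convenience only.

## The cage simulator

No public recordings of either stream exist, so validation rests on a
generator that emulates the study conditions:

* **Movement**: per animal, a continuous-time Markov walk on the grid —
  exponential holding times, jumps to a uniformly chosen rook-adjacent
  field.  The jump rate is phase-dependent: `move_rate_dark = 150/h`,
  `move_rate_light = 50/h` (12 h/12 h cycle, lights on 06:00), i.e. about
  2400 crossings per animal per day with a 3:1 dark:light ratio — the
  scale real group-housed mice show.  Every jump logs the next field's
  `IN` first and the previous field's `OUT` after a uniform 50–500 ms lag,
  exercising the dedup rule continuously.
* **Wheel bouts**: while on a wheel field, bouts start at 2/h (light) ×4
  (dark); durations are log-normal (median 75 s, σ=0.6, capped at 600 s),
  speeds normal (40 ± 10 rpm, floor 5).  Entering the wheel logs an `OUT`
  on the wheel field and suspends detection; leaving logs an `IN` on a
  wheel field.  Rotations are split across minutes by overlap and rounded
  per minute; per-minute records carry active seconds, run counts and
  speeds consistent with the bout draws.
* **Confounds**: with probability `p_bystander` per bout, another animal
  moves to a wheel field and slips under the wheel (undetectable, not
  running) for the bout's duration — the case the rule *must*
  multi-credit, since it is observationally identical to simultaneous
  exercise.  With probability `p_artifact_minute` per minute, artifact
  rotations with no animal in the wheel are injected (husbandry); these
  minutes must be discarded.  Both default to 0.
* **Ground truth** records every detection segment, every wheel spell,
  every bout and artifact.  Wheel spells are recorded from the instant the
  animal becomes *unobservable*: a doubling-lagged exit can outlive the
  wheel-entry `OUT` by up to the lag, so the first ≤0.5 s of a spell may
  still be nominally detected.  The truth describes what the instrument
  can see; rotation binning uses the true bout times.  Re-emitting the
  recorded segments reproduces the event stream byte-for-byte, and a fixed
  seed reproduces everything exactly (a single seeded generator drives all
  draws).

What the generator does **not** model: body size and biomechanics,
antenna cross-talk between cages, chip read failures, posture or distances
within a field, and the lights-on/off activity spikes real mice show.
Passing tests therefore demonstrate correctness of the reconstruction and
attribution logic under the stated detection semantics, not robustness to
every artefact of real hardware.

## Validation

* The three canonical wheel scenarios resolve exactly (credit the lone
  exerciser; ignore a detected neighbour on a wheel field; discard outside
  spinning).
* Field changes equal a naive collapse-and-count oracle and are invariant
  to inserting or removing `OUT` rows, on 1000 random legal streams.
* Occupancy intervals, flattened per millisecond, equal an event-by-event
  brute-force replay on random streams of up to 500 events.
* On seed-fixed 7-day, 4-mouse cages the gap-mode rule credits every
  wheel-active minute exactly as the ground truth predicts — 100 % with no
  confounds, and with bystanders/artifacts every confounded minute is
  multi-credited or discarded exactly as predicted (verified across 20 and
  12 seeds respectively).
* The configured dark:light rate ratio is recovered from the circadian
  profile within 3 Monte-Carlo standard errors over 20 replicate days.
* The simulate → assign → aggregate pipeline is byte-identical across runs
  with the same seed.

Problem sizes used by the default suite and the acceptance script — 7-day
cages for recovery, 20 days for rate recovery, 1000/500-event random
streams for the oracles — were chosen to give the checks thousands of
wheel-active minutes and tight Monte-Carlo error while keeping a full run
in well under a minute each.

## Numerical and format choices

* All internal time arithmetic uses integer milliseconds; boundaries are
  half-open everywhere, so no instant belongs to two windows.
* Two CSV dialects (`intl`: comma/dot/ISO dates; `de`: semicolon/comma/
  DD.MM.YYYY) with header sniffing; both date forms are accepted on read
  regardless of dialect, and `Enter`/`ENTER` both map to the direction
  column.  `MS` is ignored on `IN` rows.  The wheel export's timestamp
  column name is not standardised; the reader takes the first
  non-numeric-schema column and requires strictly increasing minutes.
* Readers are strict by default (row errors carry line numbers); a lenient
  flag skips bad rows with a logged warning.
* The animal roster defaults to all RFIDs seen in the event stream; it can
  be pinned explicitly so a failed chip is noticed rather than silently
  shrinking the roster.

## Known limitations

* Per-minute wheel aggregation fundamentally limits premise (b); the
  strictness parameter makes the trade-off explicit rather than resolving
  it.
* A bystander hiding under the wheel during a bout is observationally
  identical to a second exerciser and is credited as one; the method
  discards or multi-credits ambiguity, it never splits or infers
  probabilistically.
* Field changes are a surrogate for locomotion: movement within one field
  is invisible, and no distances or behaviours are inferred.
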