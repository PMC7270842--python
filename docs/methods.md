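# Methods

## The reasoning procedure

`alarmfap` models the false-alarm reasoning pipeline of a simulated ICU
ward as five stages:

1. **Simulation.** Scalar temperature and heart-rate readings are drawn
   per patient on a fixed cadence; alarm-context snapshots (eight inputs:
   battery level and last change, skin-preparation and electrode-change
   times, patient localization and its log, bed position and its log) are
   produced at the same instants, with artifact events injected as ground
   truth.
2. **Detection.** Each reading is screened against the patient's
   per-vital anomaly thresholds; strict violations mint alarm events with
   sequential IDs per (ward, vital) stream.
3. **Reasoning.** Four binary false-alarm indicators are computed from the
   alarm's context and aggregated into a FAP; the FAP becomes the
   notification's FAP_LABEL iff it reaches the `fap_not_min` threshold.
4. **Notification.** The first alarm of a (patient, vital) stream is sent
   immediately and opens a batch; later alarms join the batch, which is
   flushed exactly one window after opening. Delivery is unconditional —
   the FAP only annotates, never filters.
5. **Evaluation.** Label decisions are tallied against the simulator's
   injected causes ("positive" = labelled probable-false-alarm).

## Indicator rules and their parameters

The published description of the four indicators names the context inputs
each one draws on but not the activation rule, so each FAI is implemented
as a binary rule with configurable thresholds. Binary indicators are the
minimal model consistent with every observed FAP being a multiple of 25.
Within an indicator, its two inputs combine by OR, because either
condition alone is a recognized false-alarm cause.

| Parameter | Default | Meaning |
|---|---|---|
| `battery_low_threshold` | 20 % | charge below this activates the battery FAI |
| `battery_life` | 24 h | a battery older than this activates the battery FAI |
| `skin_prep_max_age` | 24 h | stale skin preparation activates the placement FAI |
| `electrode_max_age` | 24 h | stale electrodes activate the placement FAI |
| `mobility_window` | 60 s | lookback for recent localization changes |
| `repositioning_window` | 60 s | lookback for recent bed-position changes |
| `bed_location` | `"bed"` | the localization label counted as "in bed" |
| `weights` | (¼, ¼, ¼, ¼) | indicator weights, must sum to 1 |
| `fap_not_min` | 75 % | minimum FAP at which a label is attached |

A missing context input makes its indicator contribute 0 and logs a
warning. This fail-safe direction is deliberate: an unlabelled true alarm
costs nothing (the alarm is delivered regardless), whereas wrongly
labelling a genuine alarm as probably false could slow the response to it.

The label comparison is `fap >= fap_not_min` on the exact value, before
any rounding to the one-decimal display format; a FAP of exactly 75.0
against the default threshold is therefore labelled.

## The simulator: what it emulates and what it does not

Defaults: four patients in one ward with per-patient thresholds
(35.5/39.0 °C and 60/100 BPM for patient 1; 35.0/38.5 and 55/95 for
patient 2; 35.5/39.5 and 60/100 for patient 3; 35.5/38.5 and 50/100 for
patient 4), temperature uniform over 35.0–42.0 °C at 0.1 °C resolution,
heart rate uniform over the integers 40–188 BPM, one reading per patient
per vital every 2 s, and a run length of 600 s.

Choices behind those numbers:

* **Uniform sampling.** The source system describes its generator only as
  random within the stated ranges; uniform is the minimal reading, and the
  0.1 °C / 1 BPM resolutions match the precision of the reported values.
* **2 s cadence.** Reported inter-alarm gaps in the reference output run
  about 2–16 s; a 2 s cadence reproduces that density.
* **600 s run.** Ten minutes spans both the immediate-notification phase
  and two full batch windows, and is long enough (five hold durations)
  for artifact activity to decorrelate from its initial state.
* **Artifact injection.** Each of the four causes arrives per patient as
  an independent Poisson process at 12 events/hour, holding its context
  feature in the activating state for 120 s. Arrivals are generated from
  one hold before the run starts, so cause activity is stationary at
  ≈ 1 − exp(−0.4) ≈ 33 % busy per cause from the first reading rather than
  ramping up from an artificially clean start. The active-cause set is
  recorded per snapshot as hidden ground truth; the reasoner never reads
  it.
* **Sub-streams.** Every (patient, vital) and (patient, cause) pair gets
  an independent child of the run seed, so adding a patient does not
  perturb existing streams.

Context snapshots are constructed views, not an evolving device state:
the clean baseline has a full recently-changed battery, skin prepared and
electrodes changed two hours before the snapshot, the patient in bed with
a stable localization log, and a stable bed position; each injected cause
moves exactly its own feature into the activating state. By construction,
a cause is in the ground-truth set iff its indicator fires — the tests
assert this equivalence snapshot by snapshot.

What the simulator does *not* emulate: physiological waveform morphology,
autocorrelated vitals, patient deterioration, sensor drift, or any
correlation between artifact causes and the vital values themselves.
Artifact events perturb only the context, not the readings, so a "true"
alarm here is simply a threshold violation with clean context. Passing
tests therefore demonstrate the correctness of the reasoning, batching and
evaluation machinery under controlled conditions — not clinical
performance on real monitor data.

## Detection and identifier semantics

Thresholds are inclusive-normal: a value equal to a threshold does not
alarm. Every anomalous reading mints its own alarm (no debounce of
sustained violations), matching the dense alarm trains in the reference
output. Alarm IDs and notification IDs each count from 1 per (ward,
vital) stream and are shared across patients within it, which is why a
single patient's alarms show AID gaps.

## Notification timing

The batch window defaults to 300 s, the value recovered from the
reference output's opening-to-flush timestamp differences. A flushed
batch is stamped with its *scheduled* time (open timestamp + window) to
the millisecond, not with the wall clock at flush; immediate
notifications are stamped with their processing instant, which in
simulation equals the alarm timestamp (the toolkit models no transport
latency). The event clock must be monotone; time moving backwards raises
an error rather than silently corrupting batch state.

## Evaluation

An alarm's truth is "artifact" iff at least one injected cause was active
at its timestamp; predicted positive means a label was attached. With
equal weights and the default 75% threshold a label requires three or
more simultaneous causes, so against a truth of "any cause active" the
labeller is intentionally conservative: precision is typically 1.0 while
recall is low. `threshold_sweep` re-applies the decision rule across
thresholds (values above 100 are permitted there and label nothing) and
reports the monotone predicted-positive counts. Ratios with empty
denominators are reported as absent, never coerced to 0.

## Known limitations

* The FAI activation thresholds are plausible clinical defaults, not
  fitted values; nothing in the scoring is learned.
* The FAP_LABEL is computed per alarm. A notification-level aggregate for
  batches containing alarms with different FAPs is not defined; the
  per-alarm reading is the one implemented.
* Evaluation is only meaningful on simulated streams, where ground truth
  exists; replayed recorded tables cannot be scored, only relabelled.
* The in-process batcher models the message flow of a broker deployment
  but none of its delivery, acknowledgement or retry semantics.
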