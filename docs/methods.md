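# Methods

## The measurement problem

Two seated participants hand an instrumented object from giver to
receiver. The object logs the grip forces of both actors at 100 Hz via
force sensors under its two grasping surfaces (giver below, receiver
above) and flashes an infrared Sync-LED whose coded pulse trains appear
both in the force log and in the motion-capture record, so the two
streams can be aligned without cables. The analysis segments the four
handover phases and quantifies, for phase 1, the *lift delay* — the
time from first finger contact to the object rising off its pad — with
a force-based and a kinematics-based algorithm, and their difference
(*lift-delta*) as the lag between force development and grip formation.

## Sync codec

All signal durations are multiples of the 10 ms frame, so the codec
operates on frames and round trips are exact. The decoder run-length
encodes the binary track and classifies each segment by the nearest
nominal length within a jitter tolerance (default ±1 frame); a segment
within tolerance of two codes is ambiguous, and the candidate message is
discarded rather than guessed — a dropped message is recoverable, a
wrong one is not. The start pattern (20/12/6 frames) shares no
run-length structure with the bit codes (6+2 / 3+2 frames), which is
what makes start/end detection robust to LED drop-outs. Messages must be
separated by ≥5 OFF frames; the timing of the gap between the object-ID
and recording-number fields is not part of the documented protocol, and
we adopt the same 2-frame OFF used between bits. The trailing 2-frame
OFF of the last bit belongs to the message; on an idle line it merges
with the idle OFF run, which the decoder accepts.

## Event detection

- **Contact** (finger force): first frame at which *any* giver channel
  deviates from its baseline — the per-channel median of the first
  500 ms — by strictly more than 0.07 N. The per-channel reading is the
  sensitive interpretation of "any finger contacted the surface"; a
  summed-force variant would be less sensitive and is not used.
- **Lift-off**: first frame at which the object-LED centroid has risen
  at least 2 mm (inclusive) above its resting height (median of the
  500 ms before contact).
- **Transfer start**: receiver contact, by the same rule as giver
  contact (the operational criterion is not documented; mirroring the
  giver rule is the symmetric choice).
- **Release**: first frame after transfer start at which the giver's
  summed force magnitude falls and stays below 0.07 N for ≥100 ms (the
  sustain requirement suppresses flicker).
- **Approach onset**: first frame at which wrist speed exceeds 5% of the
  trial's peak speed for ≥50 ms — the standard kinematic onset rule.
- **Opposing finger**: lower SD of the finger–thumb distance over
  [lift-off, transfer start). We read "position variability" as
  variability of the *thumb-relative* distance (the opposing finger
  "remains spatially stable to the thumb"), not of absolute fingertip
  position, which would be dominated by arm transport.
- **Grip closure** (finger distance): argmin of the opposing
  finger–thumb distance on [approach onset, lift-off], ties broken to
  the latest minimizing frame (the final pre-lift closure).

No smoothing is applied by default, so the thresholds act on raw
samples and every detection equals a linear scan. A zero-phase 2nd-order
Butterworth low-pass (conventionally 10 Hz for kinematics) is available
behind a flag; on noisy markers the unsmoothed wrist-speed onset rule
fires on the differentiated noise floor, so noisy kinematic onset work
should enable it. The distance algorithm is unaffected because the rest
aperture exceeds both grip widths, keeping the distance minimum at grip
closure regardless of where the search window starts.

Undefined events are reported as `None` with a reason, never guessed;
trials with undefined required events are dropped from the cohort table
(as lost trials are in the lab).

## Synthetic-trial generator

The generator is the package's ground-truth oracle. Per trial it samples
an event schedule (approach onset ≈ 1 s, reach ≈ 800 ms, lift delay and
lift-delta from Gaussian models, transport ≈ 1.2 s, transfer ≈ 400 ms),
then synthesizes:

- **Kinematics**: minimum-jerk wrist reaches (fingertips as thumb +
  aperture along fixed grasp axes); the aperture opens past its peak and
  closes to the grip width with a linear pad-compression dip
  (0.3 mm/frame in, 0.2 mm/frame out) whose unique minimum is the
  closure event; during transport the opposing finger wiggles with
  0.15 mm SD while the torque-stabilizing finger oscillates with 2.5 mm
  amplitude at 1.5 Hz.
- **Forces**: a 0.1 N contact step (impact preload) followed by a
  smoothstep rise over 150 ms to the grip level (2 N + 6 N/kg);
  tangential forces take up m·g between contact and lift-off, hand it to
  the receiver between transfer start and release, with the giver
  unloading linearly to exactly zero at the release frame. The sharp
  onset/offset shapes give every force-defined event an exact noiseless
  target.
- **Object**: rises at 250 mm/s to 60 mm — so the 2 mm criterion is met
  one frame after motion onset — rides with the giver then receiver, and
  is set down before the recording stops.
- **Noise**: Gaussian, marker σ = 0.3 mm per coordinate and force
  σ = 0.01 N, both an order of magnitude below the detection thresholds;
  both configurable upward for stress tests.

Timing means and slopes are set so the per-condition medians land in the
published ranges (force delay ≈ 230–370 ms rising ≈ 0.2 ms/g with mass,
distance delay shorter by a 105–165 ms lift-delta, small size effects),
with 50/30 ms trial scatter; these reproduce the *direction and scale*
of the condition structure, not any specific human dataset. Finger
preference is a per-participant Bernoulli probability of using the index
finger, drawn from U(0.4, 1), whose lower bound excludes exclusive
middle-finger use. The design generator reproduces the full protocol:
six single-size blocks of 10 trials per giver, starting size
counterbalanced across dyads, weights shuffled within blocks under a
rotated 4/3/3 pattern so each size × weight cell has exactly 10
repetitions, roles switched after 60 trials.

What the generator does **not** emulate: marker occlusion and labeling
errors, torque channels, pad-conditioned friction, trial-to-trial force
ripple, receiver-side grip detail, or any coupling between finger choice
and lift-delta (the regression's slope on real data). Passing tests
therefore certify the detectors' and statistics' correctness against a
controlled signal model, not field performance on lab data.

`simulate_hold` produces exact two-digit static holds (thumb vs.
virtual finger): opposed normals, tangential halves summing to m·g
(g = 9.81 m/s²), symmetric application points cancelling all moments —
the fixture for the equilibrium checker, which reports residuals of the
four conditions and the slip margin (normal ≥ tangential/μ, default
μ = 0.8) without throwing.

## File formats

Force CSV: 10,000 rows always (zero-padded after the stop frame, as the
firmware writes it), one column per sensor component plus the binary
`sync_led` track. Marker TSV: wide `label_x/y/z` columns on the mocap
clock with its own `sync_led` column; gaps (NaN) of ≤100 ms are linearly
interpolated and flagged, longer gaps are left unfilled and flagged so
downstream detectors can invalidate. The loader re-aligns the streams
from the decoded start pulses and raises an integrity error if the
decoded end-signal payload contradicts the metadata. Torque columns are
not modeled; the schema would extend with `_tx/_ty/_tz` per sensor.

## Statistics

Medians and IQRs use linear-interpolation ("type 7") quartiles.
Factorial tests run on one aggregate (default: median) per
dyad × size × weight cell; weight is coded as an equally spaced numeric
contrast (−1, 0, +1) and size as ±1, so each factor's F-test has one
numerator degree of freedom, matching the reporting convention this
layout follows; η² is the factor's share of the total sum of squares.
The stratified regression is plain OLS of the per-cell lift-delta on
finger index and its size/weight interactions (same coding); estimates,
SEs, p-values, model F and adjusted R² come from `statsmodels`. Lift-
delta aggregation is per-trial differences then cell medians (a
differences-of-aggregates variant is a one-line change in stage 3; the
per-trial route was chosen because it is defined even when a cell loses
trials asymmetrically between algorithms).

## Problem sizes and numerical choices

The bundled analyses use 20 dyads (2,400 trials, ≈4 s to simulate and
detect); the test suite verifies noiseless frame-exact recovery on 100
trials, default-noise recovery (finger ≥95%, delay RMS ≤20 ms) on 200,
null calibration of both tests on 10,000 cell-level replicates, and
coefficient recovery on 1,500 replicates in the published regression's
coefficient regime. Noiseless lift-off is detected one frame after the
true motion-onset frame (the object must first rise 2 mm); the
approach-onset detector is checked against the closed-form 5%-of-peak
crossing of the minimum-jerk speed profile. All simulations are seeded
and bit-reproducible.
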