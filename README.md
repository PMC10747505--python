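# handover

Analysis of dyadic object-handover trials recorded with an instrumented
object: a 3D-printed test object with force sensors under its grasping
surfaces and an infrared Sync-LED that lets its 100 Hz force log be
aligned, frame-exactly, with an optical motion-capture record of both
actors. A giver reaches for the object, grasps it between thumb and
fingers, lifts it, transports it and hands it to a receiver — four
phases (reach & grasp, transport, transfer, end of handover) that this
package segments and analyzes. It is written for movement scientists
studying grip-force/kinematics coordination in joint action.

## What it computes

**Stream synchronization.** The object's Sync-LED flashes a start signal
(200 ms ON, 120 ms OFF, 60 ms ON) and an end signal carrying a 3-bit
object ID and a 7-bit recording number (bit 1 = 60 ms ON + 20 ms OFF,
bit 0 = 30 ms ON + 20 ms OFF, MSB first). `handover.sync` encodes and
decodes these trains with ±1-frame jitter tolerance and returns the
frame offset between the object and mocap clocks.

**Lift delay, two ways.** The interval from first object contact to
lift-off is computed by two algorithms:

- *finger force* — contact is the first frame at which any giver force
  channel deviates from its rest baseline by strictly more than 0.07 N;
  lift-off is the first frame at which the object has risen at least
  2 mm;
- *finger distance* — the force-opposing finger (index or middle) is the
  one whose thumb-relative distance has the lower SD during transport;
  grip formation is the frame of minimal finger–thumb distance between
  approach onset and lift-off.

Their difference, the **lift-delta**, measures how far force development
leads stable grip formation. Per participant and condition (2 object
sizes × 3 weights × 10 repetitions), finger choice is summarized by the
**finger index**

```
finger index = (N_index − N_middle) / (N_index + N_middle)   ∈ [−1, 1]
```

(+1: always the index finger opposes the thumb; −1: always the middle).
`handover.stats` reports medians/IQR per condition, single-df F
contrasts for weight (−1/0/+1) and size (±1), and the OLS regression
`lift_delta ~ finger_index + finger_index:size + finger_index:weight`.
`handover.metrics.check_equilibrium` verifies the static prismatic-grasp
conditions (thumb normal opposing the virtual-finger normal, tangential
sum carrying m·g, slip margins, zero net moment).

**Synthetic trials.** No public dataset accompanies the apparatus, so
`handover.synth` generates the full counterbalanced design and per-trial
force + marker streams with known ground-truth events — the test bed for
every detector and statistic here (see `docs/methods.md` for what the
generator does and does not emulate).

## Worked example

```
python analysis/01_simulate_experiment.py   # design + example trial bundle
python analysis/02_detect_events.py         # detectors -> per-trial table
python analysis/03_grasp_metrics.py         # finger index per cell
python analysis/04_stats_report.py          # summaries, contrasts, regression
```

With the default 20 dyads and seed 42 stage 2 prints

```
analyzed 2400 trials (0 lost to undefined events)
opposing-finger recovery: 100.0%
lift-delay RMS error: finger force 10.0 ms, finger distance 14.8 ms
```

— 2,400 trials (40 participants × 60), with the detectors recovering the
generator's true opposing finger in every trial and its true lift delays
to ≈10–15 ms. Stage 4 then prints the condition table (ms, median/IQR):

```
size                  large                               small
weight_g               400         700         1000        400         700         1000
finger_force     260.0/70.0  310.0/70.0  380.0/70.0  240.0/60.0  300.0/60.0  360.0/70.0
finger_distance  120.0/80.0  160.0/80.0  200.0/90.0  130.0/80.0  180.0/90.0  210.0/80.0
lift_delta       140.0/50.0  160.0/50.0  170.0/40.0  110.0/42.5  120.0/50.0  150.0/50.0
```

showing both lift delays rising with object weight and the lift-delta of
100–170 ms by which force development leads grip formation, plus the
factorial contrasts (e.g. `finger force ~ weight: F(1, 117) = 1502.32,
p = 1.3e-68`) and the stratified regression table. All tables land under
`results/`.

A single trial can also be driven from the shell: `handover sim`,
`handover detect --trial DIR`, `handover validate --trial DIR`,
`handover metrics`, `handover stats` (see `--help`).

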