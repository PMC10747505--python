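"""Synthetic handover-trial generator with known ground truth.

Emulates the dyadic handover experiment: a giver reaches for an
instrumented object resting on a start pad, grasps it between thumb and
two fingers, lifts it, transports it across the table, and hands it to a
receiver who places it on an end pad.  Streams are generated at the
experiment's common 100 Hz clock in the units of the real apparatus
(millimeters, newtons, +z up).

The generator is the ground-truth oracle for the event detectors and the
statistical pipeline: every trial carries the true contact, lift-off,
transfer and release frames, the true force-opposing finger and the true
object mass.  Its structural choices (minimum-jerk reaches, smoothstep
force ramps with a small contact preload, a sharp aperture minimum at
grip closure, a linear lift at constant speed, linear giver unloading)
are deliberately the simplest shapes under which the detection rules have
exact noiseless targets; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .sync import PulseTrain, encode_end, encode_start

G_M_S2 = 9.81  #: standard gravity, m/s^2

SIZES = ("small", "large")
WEIGHTS_G = (400, 700, 1000)
REPS_PER_CONDITION = 10
BLOCKS_PER_GIVER = 6
TRIALS_PER_GIVER = 60

MARKER_LABELS = (
    "g_wrist", "g_thumb", "g_index", "g_middle",
    "r_wrist", "r_thumb", "r_index", "r_middle",
    "obj_led1", "obj_led2", "obj_led3", "obj_led4", "obj_led5",
)

FORCE_CHANNELS = (
    "g_s1_fx", "g_s1_fy", "g_s1_fz", "g_s2_fx", "g_s2_fy", "g_s2_fz",
    "r_s1_fx", "r_s1_fy", "r_s1_fz", "r_s2_fx", "r_s2_fy", "r_s2_fz",
)


# ---------------------------------------------------------------------------
# experiment design


@dataclass(frozen=True)
class ExperimentPlan:
    """Full trial list of a simulated multi-dyad experiment."""

    trials: pd.DataFrame  # dyad, giver, receiver, trial_in_session, block,
                          # rep_in_block, size, weight_g, recording_number, object_id

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _block_weight_lists(rng: np.random.Generator) -> list[list[int]]:
    """Weights for the three 10-trial blocks of one size.

    Ten trials cannot split evenly over three weights, so blocks carry a
    rotated 4/3/3 pattern whose column sums are 10 per weight, shuffled
    within each block (pseudo-random, balanced within block).
    """
    counts = [(4, 3, 3), (3, 4, 3), (3, 3, 4)]
    blocks = []
    for c in counts:
        block = [w for w, k in zip(WEIGHTS_G, c) for _ in range(k)]
        rng.shuffle(block)
        blocks.append(block)
    return blocks


def design_experiment(n_dyads: int, seed: int) -> ExperimentPlan:
    """Build the counterbalanced block design.

    Per giver: 6 blocks of 10 trials, each block a single object size,
    sizes alternating with the starting size counterbalanced across
    dyads; weights pseudo-random and balanced within block so that each
    (size x weight) cell occurs exactly 10 times per giver.  Roles switch
    after the first giver's 60 trials.  Deterministic given ``seed``.
    """
    if n_dyads < 1:
        raise ValueError("n_dyads must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for dyad in range(n_dyads):
        first_size = SIZES[dyad % 2]  # counterbalanced block order
        other = SIZES[1 - dyad % 2]
        size_order = [first_size, other] * (BLOCKS_PER_GIVER // 2)
        participants = (f"d{dyad:02d}a", f"d{dyad:02d}b")
        recording = 0
        for half, giver in enumerate(participants):
            receiver = participants[1 - half]
            per_size = {s: iter(_block_weight_lists(rng)) for s in SIZES}
            trial_in_session = half * TRIALS_PER_GIVER
            for block, size in enumerate(size_order):
                weights = next(per_size[size])
                for rep, w in enumerate(weights):
                    rows.append(
                        dict(
                            dyad=dyad,
                            giver=giver,
                            receiver=receiver,
                            trial_in_session=trial_in_session,
                            block=block,
                            rep_in_block=rep,
                            size=size,
                            weight_g=w,
                            recording_number=recording,
                            object_id=(4 if size == "large" else 2),
                        )
                    )
                    trial_in_session += 1
                    recording += 1
    return ExperimentPlan(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# generator parameters


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable knobs of the trial generator (times ms, lengths mm, forces N).

    Defaults are the package's reference conditions: sensor noise well
    below the detection thresholds (0.07 N force change, 2 mm lift), a
    weight -> lift-delay slope oriented and scaled like the published
    condition medians, and per-participant finger preference excluding
    exclusive middle-finger use.
    """

    marker_noise_mm: float = 0.3
    force_noise_n: float = 0.01

    # force development
    contact_preload_n: float = 0.1   # impact step at first contact
    force_rise_ms: float = 150.0     # smoothstep rise time to grip level
    base_grip_n: float = 2.0
    grip_per_kg_n: float = 6.0

    # lift kinematics
    lift_speed_mm_s: float = 250.0
    lift_height_mm: float = 60.0
    object_rest_z_mm: float = 40.0

    # reach timing
    move_onset_ms: float = 1000.0
    move_onset_jitter_ms: float = 100.0
    reach_ms: float = 800.0
    reach_sd_ms: float = 50.0

    # lift delay (force algorithm target): contact -> lift-off
    delay_force_base_ms: float = 230.0      # at 400 g, small object
    delay_force_slope_ms_per_g: float = 0.2
    delay_force_size_ms: float = 15.0       # additional delay, large object
    delay_force_sd_ms: float = 50.0
    delay_force_min_ms: float = 80.0

    # lift-delta (force minus distance algorithm): contact -> grip closure
    delta_base_ms: float = 105.0
    delta_slope_ms_per_g: float = 0.06
    delta_size_ms: float = 30.0
    delta_sd_ms: float = 30.0
    delta_min_ms: float = 20.0
    delay_distance_min_ms: float = 30.0

    # transport / transfer timing
    transport_ms: float = 1200.0
    transport_sd_ms: float = 100.0
    transfer_ms: float = 400.0
    transfer_sd_ms: float = 50.0

    # grip geometry and aperture shape
    grip_width_small_mm: float = 50.0
    grip_width_large_mm: float = 80.0
    # rest aperture must exceed both grip widths, otherwise the minimal
    # finger-thumb distance in the approach->lift-off window would sit in
    # the rest pose rather than at grip closure
    aperture_rest_mm: float = 90.0
    aperture_peak_mm: float = 110.0
    closure_slope_mm_per_frame: float = 0.3   # pad compression into the minimum
    rebound_slope_mm_per_frame: float = 0.2
    rebound_mm: float = 2.0

    # transport-phase finger variability (opposing vs. torque-stabilizing)
    opp_wiggle_mm: float = 0.15
    other_wiggle_amp_mm: float = 2.5
    other_wiggle_hz: float = 1.5

    # finger preference: per-participant P(index opposes) ~ U(lo, hi);
    # lo > 0 excludes exclusive middle-finger use
    p_index_low: float = 0.4
    p_index_high: float = 1.0

    mu_friction: float = 0.8

    def grip_width_mm(self, size: str) -> float:
        return self.grip_width_small_mm if size == "small" else self.grip_width_large_mm


DEFAULT_PARAMS = GeneratorParams()

NOISELESS = replace(
    DEFAULT_PARAMS, marker_noise_mm=0.0, force_noise_n=0.0,
    opp_wiggle_mm=0.0,
)


# ---------------------------------------------------------------------------
# ground truth / recording containers


@dataclass(frozen=True)
class GroundTruth:
    """True event frames and trial facts of one synthetic trial."""

    true_move_onset_frame: int      # wrist starts moving (reach onset)
    true_contact_frame: int         # first finger contact on the surface
    true_closure_frame: int         # opposing finger-thumb distance minimal
    true_liftoff_frame: int         # object leaves the pad
    true_transfer_start_frame: int  # receiver first contact
    true_release_frame: int         # giver fully unloaded
    true_stop_frame: int            # last real sample of the force log
    true_opposing_finger: Literal["index", "middle"]
    object_mass_g: int
    mocap_offset_frames: int        # mocap clock lead over the object clock

    def __post_init__(self) -> None:
        seq = (
            self.true_move_onset_frame,
            self.true_contact_frame,
            self.true_closure_frame,
            self.true_liftoff_frame,
            self.true_transfer_start_frame,
            self.true_release_frame,
            self.true_stop_frame,
        )
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"ground-truth events must strictly increase: {seq}")
        if self.object_mass_g not in WEIGHTS_G:
            raise ValueError(f"mass {self.object_mass_g} g not a study weight")

    @property
    def delay_force_ms(self) -> float:
        return (self.true_liftoff_frame - self.true_contact_frame) * 10.0

    @property
    def delay_distance_ms(self) -> float:
        return (self.true_liftoff_frame - self.true_closure_frame) * 10.0


@dataclass
class TrialRecording:
    """Aligned multichannel bundle of one trial (object clock, 100 Hz).

    ``markers`` maps label -> (n, 3) float array in mm (+z up);
    ``forces`` maps channel -> (n,) float array in N; ``sync`` is the
    object's Sync-LED logic track.  ``n = stop_frame`` real samples; the
    on-disk force log is zero-padded beyond that, the in-memory bundle is
    not.
    """

    markers: dict[str, np.ndarray]
    forces: dict[str, np.ndarray]
    sync: PulseTrain
    meta: dict
    stop_frame: int
    marker_gap_flags: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.stop_frame

    def object_led_centroid(self) -> np.ndarray:
        leds = [self.markers[k] for k in self.markers if k.startswith("obj_led")]
        return np.mean(leds, axis=0)


# ---------------------------------------------------------------------------
# primitive profiles


def min_jerk(p0: np.ndarray, p1: np.ndarray, n: int) -> np.ndarray:
    """Minimum-jerk interpolation from p0 to p1 over n frames (inclusive ends)."""
    tau = np.linspace(0.0, 1.0, n)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return p0[None, :] + s[:, None] * (p1 - p0)[None, :]


def min_jerk_speed_crossing_tau(fraction: float) -> float:
    """Normalized time at which the minimum-jerk speed profile first
    exceeds ``fraction`` of its peak (closed form).

    Speed is v(tau) = 30 tau^2 (1-tau)^2 x (D/T) with peak 1.875 D/T at
    tau = 1/2, so the crossing solves tau(1-tau) = sqrt(fraction x
    1.875 / 30).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    c = math.sqrt(fraction * 1.875 / 30.0)
    return (1.0 - math.sqrt(1.0 - 4.0 * c)) / 2.0


def _cos_ease(a: float, b: float, n: int) -> np.ndarray:
    tau = np.linspace(0.0, 1.0, n)
    return a + (b - a) * (1 - np.cos(np.pi * tau)) / 2


def _smoothstep(n: int) -> np.ndarray:
    tau = np.linspace(0.0, 1.0, n)
    return 3 * tau**2 - 2 * tau**3


# ---------------------------------------------------------------------------
# event schedule


def _sample_events(row: dict, p: GeneratorParams, rng: np.random.Generator) -> dict:
    """Sample the trial's true event frames from the timing model."""
    mass = int(row["weight_g"])
    large = row["size"] == "large"

    t0 = int(round((p.move_onset_ms + rng.uniform(-1, 1) * p.move_onset_jitter_ms) / 10))
    reach = max(40, int(round(rng.normal(p.reach_ms, p.reach_sd_ms) / 10)))
    contact = t0 + reach

    df_ms = rng.normal(
        p.delay_force_base_ms
        + p.delay_force_slope_ms_per_g * (mass - WEIGHTS_G[0])
        + (p.delay_force_size_ms if large else 0.0),
        p.delay_force_sd_ms,
    )
    df_ms = max(p.delay_force_min_ms, df_ms)
    delta_ms = rng.normal(
        p.delta_base_ms
        + p.delta_slope_ms_per_g * (mass - WEIGHTS_G[0])
        + (p.delta_size_ms if large else 0.0),
        p.delta_sd_ms,
    )
    delta_ms = min(max(p.delta_min_ms, delta_ms), df_ms - p.delay_distance_min_ms)

    liftoff = contact + int(round(df_ms / 10))
    closure = contact + int(round(delta_ms / 10))
    closure = min(max(closure, contact + 2), liftoff - 2)

    transfer = liftoff + max(40, int(round(rng.normal(p.transport_ms, p.transport_sd_ms) / 10)))
    release = transfer + max(15, int(round(rng.normal(p.transfer_ms, p.transfer_sd_ms) / 10)))
    place = release + 100
    stop = place + 60
    if stop > 10_000:
        raise ValueError("event schedule exceeds the 100 s recording window")
    return dict(
        t0=t0, contact=contact, closure=closure, liftoff=liftoff,
        transfer=transfer, release=release, place=place, stop=stop,
    )


# ---------------------------------------------------------------------------
# stream synthesis


_GIVER_REST = np.array([60.0, -320.0, 60.0])
_GRASP_POS = np.array([40.0, -60.0, 50.0])
_HANDOVER_POS = np.array([40.0, 180.0, 120.0])
_RECV_REST = np.array([-60.0, 520.0, 60.0])
_THUMB_OFFSET = np.array([30.0, 40.0, -20.0])
_U_INDEX = np.array([0.2, 1.0, 0.05]) / np.linalg.norm([0.2, 1.0, 0.05])
_U_MIDDLE = np.array([-0.15, 1.0, 0.1]) / np.linalg.norm([-0.15, 1.0, 0.1])
_OBJ_LED_OFFSETS = np.array(
    [[25, 25, -10], [-25, 25, -10], [-25, -25, -10], [25, -25, -10], [0, 0, 15]],
    dtype=float,
)


def _piecewise_wrist(ev: dict, n: int) -> np.ndarray:
    """Giver wrist: rest -> reach -> hold -> transport -> hold -> return."""
    w = np.empty((n, 3))
    w[: ev["t0"]] = _GIVER_REST
    w[ev["t0"] : ev["contact"] + 1] = min_jerk(
        _GIVER_REST, _GRASP_POS, ev["contact"] - ev["t0"] + 1
    )
    w[ev["contact"] : ev["liftoff"] + 1] = _GRASP_POS
    w[ev["liftoff"] : ev["transfer"] + 1] = min_jerk(
        _GRASP_POS, _HANDOVER_POS, ev["transfer"] - ev["liftoff"] + 1
    )
    w[ev["transfer"] : ev["release"] + 1] = _HANDOVER_POS
    # unhurried partial return, slow enough that the reach stroke keeps
    # the trial's peak wrist speed (the approach-onset reference point)
    midway = _HANDOVER_POS + 0.5 * (_GIVER_REST - _HANDOVER_POS)
    back = min(n, ev["release"] + 150)
    w[ev["release"] : back] = min_jerk(_HANDOVER_POS, midway, back - ev["release"])
    w[back:] = midway
    return w


def _aperture(
    ev: dict, closure: int, plateau_noise: np.ndarray, p: GeneratorParams,
    grip_mm: float, n: int,
) -> np.ndarray:
    """Finger-thumb distance profile with a sharp minimum at ``closure``.

    The pad compresses linearly into the minimum at
    ``closure_slope_mm_per_frame`` and rebounds at
    ``rebound_slope_mm_per_frame`` (capped at ``rebound_mm``), so the
    argmin is unique and steep on both sides; ``plateau_noise`` is added
    from lift-off onward (transport-phase variability).
    """
    d = np.empty(n)
    t0, contact = ev["t0"], ev["contact"]
    d_contact = grip_mm + p.closure_slope_mm_per_frame * (closure - contact)
    t_peak = t0 + int(0.4 * (contact - t0))
    d[:t0] = p.aperture_rest_mm
    d[t0 : t_peak + 1] = _cos_ease(p.aperture_rest_mm, p.aperture_peak_mm, t_peak - t0 + 1)
    d[t_peak : contact + 1] = _cos_ease(p.aperture_peak_mm, d_contact, contact - t_peak + 1)
    # compression into the minimum, then rebound to a plateau
    frames = np.arange(n)
    seg = slice(contact, n)
    rel = frames[seg] - closure
    dip = np.where(
        rel <= 0,
        grip_mm - p.closure_slope_mm_per_frame * rel,
        grip_mm + np.minimum(p.rebound_slope_mm_per_frame * rel, p.rebound_mm),
    )
    d[seg] = dip
    d[ev["liftoff"] :] += plateau_noise[ev["liftoff"] :]
    return d


def _force_profile(ev: dict, mass_g: int, p: GeneratorParams, n: int) -> dict[str, np.ndarray]:
    """Per-channel giver/receiver force traces (N), zero outside contact.

    Normal force (x): preload step at contact then smoothstep to the grip
    level over ``force_rise_ms``.  Tangential force (z): each actor's two
    sensors share the gravity load m g equally; the load transfers onto
    the giver's grip between contact and lift-off, onto the receiver's
    between transfer start and giver release, and back to the support at
    placement.  The giver unloads linearly to exactly zero at the release
    frame, which makes the release event sharp.
    """
    g_n = np.zeros(n)
    g_t = np.zeros(n)
    r_n = np.zeros(n)
    r_t = np.zeros(n)
    grip = p.base_grip_n + p.grip_per_kg_n * mass_g / 1000.0
    load = mass_g / 1000.0 * G_M_S2
    rise = max(2, int(round(p.force_rise_ms / 10)))

    c, lo, tr, rel, pl = ev["contact"], ev["liftoff"], ev["transfer"], ev["release"], ev["place"]
    # giver normal: preload + smoothstep rise, hold, linear unload to 0 at release
    up = min(n, c + rise)
    g_n[c:up] = p.contact_preload_n + (grip - p.contact_preload_n) * _smoothstep(up - c)
    g_n[up:rel] = grip
    g_n[tr:rel] = grip * np.linspace(1.0, 0.0, rel - tr, endpoint=False)
    # giver tangential: load uptake from contact to lift-off, hold, linear handoff
    g_t[c:lo] = load * _smoothstep(lo - c)
    g_t[lo:tr] = load
    g_t[tr:rel] = load * np.linspace(1.0, 0.0, rel - tr, endpoint=False)
    # receiver: preload + rise at transfer start; load uptake to giver release
    r_up = min(n, tr + rise)
    r_n[tr:r_up] = p.contact_preload_n + (grip - p.contact_preload_n) * _smoothstep(r_up - tr)
    r_n[r_up:pl] = grip
    r_t[tr:rel] = load * _smoothstep(rel - tr)
    r_t[rel:pl] = load
    # receiver sets the object down over the 30 frames before `place`,
    # then opens the grip
    down0 = max(rel, pl - 30)
    r_t[down0:pl] = load * np.linspace(1.0, 0.0, pl - down0, endpoint=False)
    open_end = min(n, pl + 20)
    r_n[pl:open_end] = grip * np.linspace(1.0, 0.0, open_end - pl, endpoint=False)
    r_n[open_end:] = 0.0

    half = 0.5
    return {
        "g_s1_fx": g_n, "g_s1_fy": np.zeros(n), "g_s1_fz": half * g_t,
        "g_s2_fx": -g_n, "g_s2_fy": np.zeros(n), "g_s2_fz": half * g_t,
        "r_s1_fx": r_n, "r_s1_fy": np.zeros(n), "r_s1_fz": half * r_t,
        "r_s2_fx": -r_n, "r_s2_fy": np.zeros(n), "r_s2_fz": half * r_t,
    }


def _object_z(ev: dict, p: GeneratorParams, n: int) -> np.ndarray:
    """Object center height: linear rise at ``lift_speed_mm_s`` from
    lift-off, plateau, linear set-down ending at ``place``."""
    z = np.full(n, p.object_rest_z_mm)
    per_frame = p.lift_speed_mm_s / 100.0
    rise_frames = int(math.ceil(p.lift_height_mm / per_frame))
    lo, pl = ev["liftoff"], ev["place"]
    up = min(n, lo + rise_frames)
    z[lo:up] = p.object_rest_z_mm + per_frame * np.arange(up - lo)
    top = z[up - 1] if up > lo else p.object_rest_z_mm
    z[up:pl] = top
    down0 = max(lo, pl - rise_frames)
    z[down0:pl] = np.linspace(top, p.object_rest_z_mm, pl - down0, endpoint=False)
    z[pl:] = p.object_rest_z_mm
    return z


def _sync_track(ev: dict, row: dict, n: int) -> PulseTrain:
    states = np.zeros(n, np.uint8)
    start = encode_start().states
    states[: start.size] = start
    end = encode_end(int(row["object_id"]), int(row["recording_number"])).states
    onset = ev["stop"] - end.size - 5
    states[onset : onset + end.size] = end
    return PulseTrain(states)


def simulate_trial(
    plan_row, params: GeneratorParams = DEFAULT_PARAMS, seed: int = 0,
    p_index: float | None = None,
) -> tuple[TrialRecording, GroundTruth]:
    """Simulate one handover trial from a design row.

    ``plan_row`` is a mapping (or DataFrame row) with at least size,
    weight_g, object_id and recording_number.  ``p_index`` overrides the
    probability that the index finger opposes the thumb (otherwise drawn
    per call from the participant-preference distribution).  Returns the
    aligned recording and its ground truth; deterministic given seed.
    """
    row = dict(plan_row)
    p = params
    rng = np.random.default_rng(seed)
    ev = _sample_events(row, p, rng)
    n = ev["stop"]

    if p_index is None:
        p_index = rng.uniform(p.p_index_low, p.p_index_high)
    opposing = "index" if rng.uniform() < p_index else "middle"
    other = "middle" if opposing == "index" else "index"

    grip = p.grip_width_mm(row["size"])
    wrist = _piecewise_wrist(ev, n)
    thumb = wrist + _THUMB_OFFSET

    t = np.arange(n) / 100.0
    opp_noise = rng.normal(0.0, p.opp_wiggle_mm, n)
    phase = rng.uniform(0, 2 * np.pi)
    other_noise = p.other_wiggle_amp_mm * np.sin(
        2 * np.pi * p.other_wiggle_hz * t + phase
    )
    closure_other = max(ev["contact"] + 1, ev["closure"] - 6)
    d_opp = _aperture(ev, ev["closure"], opp_noise, p, grip, n)
    d_other = _aperture(ev, closure_other, other_noise, p, grip + 4.0, n)

    u = {"index": _U_INDEX, "middle": _U_MIDDLE}
    markers = {
        "g_wrist": wrist,
        "g_thumb": thumb,
        f"g_{opposing}": thumb + d_opp[:, None] * u[opposing][None, :],
        f"g_{other}": thumb + d_other[:, None] * u[other][None, :],
    }

    # receiver: rest, min-jerk reach arriving at transfer start, handover
    # hold, transport to the end pad, return
    rw = np.empty((n, 3))
    r_reach0 = max(0, ev["transfer"] - 70)
    rw[:r_reach0] = _RECV_REST
    rw[r_reach0 : ev["transfer"] + 1] = min_jerk(
        _RECV_REST, _HANDOVER_POS + np.array([0.0, 60.0, 30.0]),
        ev["transfer"] - r_reach0 + 1,
    )
    rw[ev["transfer"] : ev["place"] + 1] = min_jerk(
        _HANDOVER_POS + np.array([0.0, 60.0, 30.0]),
        np.array([-40.0, 420.0, 60.0]),
        ev["place"] - ev["transfer"] + 1,
    )
    back = min(n, ev["place"] + 80)
    rw[ev["place"] : back] = min_jerk(
        np.array([-40.0, 420.0, 60.0]), _RECV_REST, back - ev["place"]
    )
    rw[back:] = _RECV_REST
    markers["r_wrist"] = rw
    markers["r_thumb"] = rw + _THUMB_OFFSET
    markers["r_index"] = rw + _THUMB_OFFSET + 50.0 * _U_INDEX
    markers["r_middle"] = rw + _THUMB_OFFSET + 52.0 * _U_MIDDLE

    # object: rests on the pad, rises at lift-off, rides with the giver
    # grasp point horizontally, placed at the end pad
    z = _object_z(ev, p, n)
    center = np.empty((n, 3))
    center[: ev["liftoff"], :2] = [0.0, -80.0]
    lo, tr = ev["liftoff"], ev["transfer"]
    center[lo:tr, :2] = np.array([0.0, -80.0]) + (wrist[lo:tr, :2] - wrist[lo, :2])
    at_transfer = np.array([0.0, -80.0]) + (wrist[tr, :2] - wrist[lo, :2])
    center[tr:, :2] = at_transfer + (rw[tr:, :2] - rw[tr, :2])
    center[:, 2] = z
    for i, off in enumerate(_OBJ_LED_OFFSETS, start=1):
        markers[f"obj_led{i}"] = center + off[None, :]

    if p.marker_noise_mm > 0:
        for k in markers:
            markers[k] = markers[k] + rng.normal(0.0, p.marker_noise_mm, (n, 3))

    forces = _force_profile(ev, row["weight_g"], p, n)
    if p.force_noise_n > 0:
        for k in forces:
            noisy = forces[k].copy()
            active = noisy != 0
            noisy[active] += rng.normal(0.0, p.force_noise_n, int(active.sum()))
            forces[k] = noisy

    offset = int(rng.integers(20, 80))
    truth = GroundTruth(
        true_move_onset_frame=ev["t0"],
        true_contact_frame=ev["contact"],
        true_closure_frame=ev["closure"],
        true_liftoff_frame=ev["liftoff"],
        true_transfer_start_frame=ev["transfer"],
        true_release_frame=ev["release"],
        true_stop_frame=ev["stop"],
        true_opposing_finger=opposing,
        object_mass_g=int(row["weight_g"]),
        mocap_offset_frames=offset,
    )
    meta = {
        "object_id": int(row["object_id"]),
        "recording_number": int(row["recording_number"]),
        "size": row["size"],
        "weight_g": int(row["weight_g"]),
        "dyad": row.get("dyad"),
        "giver": row.get("giver"),
        "receiver": row.get("receiver"),
    }
    rec = TrialRecording(
        markers=markers,
        forces=forces,
        sync=_sync_track(ev, row, n),
        meta=meta,
        stop_frame=n,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# static hold snapshots


@dataclass(frozen=True)
class ForceSnapshot:
    """Stationary two-digit (thumb + virtual finger) hold state.

    Normal forces act along x (thumb pushes +x, virtual finger -x),
    tangential forces along +z (supporting the load); application points
    are in mm relative to the geometric center of the grasped surface
    pair.
    """

    thumb_normal: np.ndarray
    thumb_tangential: np.ndarray
    thumb_point: np.ndarray
    vf_normal: np.ndarray
    vf_tangential: np.ndarray
    vf_point: np.ndarray
    mass_g: float


def simulate_hold(
    mass_g: float,
    thumb_normal_n: float | None = None,
    mu: float = DEFAULT_PARAMS.mu_friction,
    grip_width_mm: float = DEFAULT_PARAMS.grip_width_small_mm,
) -> ForceSnapshot:
    """Exact static-equilibrium hold of the object at rest in the air.

    The thumb normal equals and opposes the virtual-finger normal, the
    two tangential forces split the gravity load m g equally, and the
    symmetric application points cancel all moments about the grasp
    center.  Raises if the requested normal force cannot prevent slip
    (normal < tangential / mu).
    """
    load = mass_g / 1000.0 * G_M_S2
    t_each = load / 2.0
    if thumb_normal_n is None:
        thumb_normal_n = max(2.0, 1.5 * t_each / mu if mu > 0 else 2.0)
    if mu <= 0 or thumb_normal_n * mu < t_each - 1e-12:
        raise ValueError(
            f"slip: normal {thumb_normal_n} N cannot support tangential "
            f"{t_each:.3f} N at mu={mu}"
        )
    half_w = grip_width_mm / 2.0
    return ForceSnapshot(
        thumb_normal=np.array([thumb_normal_n, 0.0, 0.0]),
        thumb_tangential=np.array([0.0, 0.0, t_each]),
        thumb_point=np.array([-half_w, 0.0, 0.0]),
        vf_normal=np.array([-thumb_normal_n, 0.0, 0.0]),
        vf_tangential=np.array([0.0, 0.0, t_each]),
        vf_point=np.array([half_w, 0.0, 0.0]),
        mass_g=float(mass_g),
    )
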