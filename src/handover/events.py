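"""Handover phase segmentation and the two lift-delay algorithms.

A handover has four phases: (1) reach and grasp, (2) object transport,
(3) object transfer, (4) end of handover.  The analysis of phase 1
hinges on two complementary definitions of the lift delay — the interval
from first object contact to lift-off:

* **finger force** — contact is the first frame at which any giver force
  channel deviates from its pre-trial baseline by strictly more than
  0.07 N; lift-off is the first frame at which the object has risen at
  least 2 mm; the delay is their separation.
* **finger distance** — the force-opposing finger (the one whose
  thumb-relative distance is most stable during transport) is identified
  first; grip formation is taken as the frame of minimal finger-thumb
  distance between approach onset and lift-off; the delay runs from that
  minimum to lift-off.

Frames are at 100 Hz, so one frame is 10 ms.  Undefined events are
represented as ``None`` with a reason in the quality flags, never as a
guessed frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .synth import TrialRecording

FORCE_CHANGE_THRESHOLD_N = 0.07  # strict: "more than"
LIFT_THRESHOLD_MM = 2.0          # inclusive: "at least"
BASELINE_WINDOW_FRAMES = 50      # 500 ms
RELEASE_SUSTAIN_FRAMES = 10      # 100 ms below threshold
ONSET_PEAK_FRACTION = 0.05
ONSET_SUSTAIN_FRAMES = 5         # 50 ms above threshold
MIN_TRANSPORT_FRAMES = 10        # 100 ms window for finger identification


class UndefinedEventError(ValueError):
    """An event required by a downstream computation is undefined."""


@dataclass
class HandoverEvents:
    """Detected frame indices of one trial (None = undefined)."""

    approach_onset_frame: int | None = None
    contact_frame: int | None = None
    liftoff_frame: int | None = None
    transfer_start_frame: int | None = None
    release_frame: int | None = None
    end_frame: int | None = None
    quality: dict[str, str] = field(default_factory=dict)

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, f"{n}_frame") is None]
        if missing:
            raise UndefinedEventError(f"undefined events: {missing}")


@dataclass(frozen=True)
class LiftDelayRecord:
    """Per-trial lift delays (ms) from both algorithms."""

    delay_force_ms: float
    delay_distance_ms: float
    opposing_finger: Literal["index", "middle"]

    @property
    def lift_delta_ms(self) -> float:
        return self.delay_force_ms - self.delay_distance_ms


# ---------------------------------------------------------------------------
# detectors


def _channel_matrix(forces: dict[str, np.ndarray], actor: str) -> np.ndarray:
    keys = sorted(k for k in forces if k.startswith(f"{actor}_"))
    if not keys:
        raise ValueError(f"no force channels for actor {actor!r}")
    return np.column_stack([forces[k] for k in keys])


def detect_contact_onset(
    giver_forces: dict[str, np.ndarray] | np.ndarray,
    threshold_n: float = FORCE_CHANGE_THRESHOLD_N,
    baseline_frames: int = BASELINE_WINDOW_FRAMES,
) -> int | None:
    """First frame where any channel deviates from its baseline by
    strictly more than ``threshold_n``.

    The baseline is the per-channel median of the first
    ``baseline_frames`` samples (the pre-trial rest).  Returns None when
    no channel ever crosses.
    """
    x = (
        _channel_matrix(giver_forces, "g")
        if isinstance(giver_forces, dict)
        else np.atleast_2d(np.asarray(giver_forces, float).T).T
    )
    baseline = np.median(x[:baseline_frames], axis=0)
    dev = np.abs(x - baseline[None, :])
    hits = np.flatnonzero((dev > threshold_n).any(axis=1))
    return int(hits[0]) if hits.size else None


def detect_liftoff(
    object_z: np.ndarray,
    baseline: float,
    threshold_mm: float = LIFT_THRESHOLD_MM,
    search_from: int = 0,
) -> int | None:
    """First frame (>= search_from) with z - baseline >= threshold (inclusive)."""
    z = np.asarray(object_z, float)
    hits = np.flatnonzero(z[search_from:] - baseline >= threshold_mm)
    return int(hits[0]) + search_from if hits.size else None


def detect_transfer(
    giver_forces: dict[str, np.ndarray],
    receiver_forces: dict[str, np.ndarray],
    threshold_n: float = FORCE_CHANGE_THRESHOLD_N,
    sustain_frames: int = RELEASE_SUSTAIN_FRAMES,
) -> tuple[int | None, int | None]:
    """(transfer_start, release).

    Transfer start is the receiver's contact onset (same rule as the
    giver's).  Release is the first frame after transfer start where the
    giver's total grip-force magnitude falls and stays below the
    threshold for at least ``sustain_frames`` frames.
    """
    r = receiver_forces if isinstance(receiver_forces, np.ndarray) else _channel_matrix(
        receiver_forces, "r"
    )
    transfer_start = detect_contact_onset(r, threshold_n)
    if transfer_start is None:
        return None, None
    g = _channel_matrix(giver_forces, "g") if isinstance(giver_forces, dict) else giver_forces
    total = np.abs(g).sum(axis=1)
    below = total < threshold_n
    release = None
    i = transfer_start
    n = below.size
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= sustain_frames or j == n:
                release = i
                break
            i = j
        else:
            i += 1
    return transfer_start, release


def lowpass(x: np.ndarray, cutoff_hz: float, frame_rate: float = 100.0) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth low-pass along axis 0."""
    from scipy.signal import butter, filtfilt

    b, a = butter(2, cutoff_hz / (frame_rate / 2.0))
    return filtfilt(b, a, np.asarray(x, float), axis=0)


def wrist_speed(
    wrist_xyz: np.ndarray, frame_rate: float = 100.0,
    smooth_hz: float | None = None,
) -> np.ndarray:
    """Wrist speed (mm/s) from central differences of the trajectory,
    optionally low-passed first (zero-phase)."""
    xyz = np.asarray(wrist_xyz, float)
    if smooth_hz is not None:
        xyz = lowpass(xyz, smooth_hz, frame_rate)
    v = np.gradient(xyz, axis=0) * frame_rate
    return np.linalg.norm(v, axis=1)


def detect_approach_onset(
    speed: np.ndarray,
    peak_fraction: float = ONSET_PEAK_FRACTION,
    sustain_frames: int = ONSET_SUSTAIN_FRAMES,
) -> int | None:
    """First frame where speed strictly exceeds ``peak_fraction`` of the
    trial's peak speed and remains above for ``sustain_frames`` frames."""
    s = np.asarray(speed, float)
    peak = s.max(initial=0.0)
    if peak <= 0.0:
        return None
    thresh = peak_fraction * peak
    above = s > thresh
    n = above.size
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= sustain_frames:
                return i
            i = j
        else:
            i += 1
    return None


def identify_opposing_finger(
    index_thumb_dist: np.ndarray,
    middle_thumb_dist: np.ndarray,
    liftoff_frame: int,
    transfer_start_frame: int,
) -> tuple[Literal["index", "middle"], bool]:
    """Finger with the lower distance-to-thumb SD over the transport
    phase [liftoff, transfer_start).

    Returns (finger, reliable); the window is unreliable when shorter
    than 100 ms.
    """
    window = slice(liftoff_frame, transfer_start_frame)
    n = transfer_start_frame - liftoff_frame
    sd_index = float(np.std(index_thumb_dist[window]))
    sd_middle = float(np.std(middle_thumb_dist[window]))
    finger = "index" if sd_index <= sd_middle else "middle"
    return finger, n >= MIN_TRANSPORT_FRAMES


def lift_delay_force(contact_frame: int, liftoff_frame: int) -> float:
    """(liftoff - contact) x 10 ms."""
    if contact_frame is None or liftoff_frame is None:
        raise UndefinedEventError("contact and lift-off must both be defined")
    return (liftoff_frame - contact_frame) * 10.0


def lift_delay_distance(
    opposing_dist: np.ndarray,
    approach_onset_frame: int,
    liftoff_frame: int,
) -> tuple[float, int]:
    """Delay (ms) from minimal finger-thumb distance to lift-off.

    The argmin is searched on [approach_onset, liftoff] inclusive; ties
    break to the latest minimizing frame (final pre-lift closure).
    Returns (delay_ms, argmin_frame).
    """
    if approach_onset_frame is None or liftoff_frame is None:
        raise UndefinedEventError("approach onset and lift-off must be defined")
    window = np.asarray(opposing_dist, float)[approach_onset_frame : liftoff_frame + 1]
    if window.size == 0:
        raise UndefinedEventError("empty search window for grip closure")
    m = window.min()
    closure = approach_onset_frame + int(np.flatnonzero(window == m)[-1])
    return (liftoff_frame - closure) * 10.0, closure


# ---------------------------------------------------------------------------
# whole-trial driver


def finger_thumb_distance(rec: TrialRecording, finger: str, actor: str = "g") -> np.ndarray:
    return np.linalg.norm(
        rec.markers[f"{actor}_{finger}"] - rec.markers[f"{actor}_thumb"], axis=1
    )


def detect_events(
    rec: TrialRecording,
    force_threshold_n: float = FORCE_CHANGE_THRESHOLD_N,
    lift_threshold_mm: float = LIFT_THRESHOLD_MM,
    smooth_kinematics_hz: float | None = None,
) -> HandoverEvents:
    """Run all detectors on an aligned trial recording.

    No smoothing is applied by default so that the thresholds act on
    the raw samples; ``smooth_kinematics_hz`` enables a zero-phase
    low-pass (10 Hz is the conventional choice) before the wrist-speed
    onset rule, which is advisable on noisy marker data.
    """
    ev = HandoverEvents()
    ev.contact_frame = detect_contact_onset(rec.forces, force_threshold_n)
    if ev.contact_frame is None:
        ev.quality["contact"] = "no force change above threshold"

    speed = wrist_speed(rec.markers["g_wrist"], smooth_hz=smooth_kinematics_hz)
    ev.approach_onset_frame = detect_approach_onset(speed)
    if ev.approach_onset_frame is None:
        ev.quality["approach_onset"] = "no sustained wrist movement"

    if ev.contact_frame is not None:
        z = rec.object_led_centroid()[:, 2]
        b0 = max(0, ev.contact_frame - BASELINE_WINDOW_FRAMES)
        baseline = float(np.median(z[b0 : ev.contact_frame]))
        ev.liftoff_frame = detect_liftoff(
            z, baseline, lift_threshold_mm, search_from=ev.contact_frame
        )
        if ev.liftoff_frame is None:
            ev.quality["liftoff"] = "object never rose 2 mm"

    transfer, release = detect_transfer(rec.forces, rec.forces, force_threshold_n)
    ev.transfer_start_frame = transfer
    ev.release_frame = release
    if transfer is None:
        ev.quality["transfer_start"] = "no receiver contact"
    elif release is None:
        ev.quality["release"] = "giver grip never released"
    ev.end_frame = rec.stop_frame
    return ev


def analyze_trial(
    rec: TrialRecording,
    events: HandoverEvents | None = None,
) -> LiftDelayRecord:
    """Both lift-delay algorithms on one trial.

    Raises :class:`UndefinedEventError` when a required event is missing
    (callers treat such trials as lost, as in the lab workflow).
    """
    ev = events if events is not None else detect_events(rec)
    ev.require("contact", "liftoff", "transfer_start", "approach_onset")
    d_index = finger_thumb_distance(rec, "index")
    d_middle = finger_thumb_distance(rec, "middle")
    finger, reliable = identify_opposing_finger(
        d_index, d_middle, ev.liftoff_frame, ev.transfer_start_frame
    )
    if not reliable:
        ev.quality["opposing_finger"] = "transport window shorter than 100 ms"
    delay_f = lift_delay_force(ev.contact_frame, ev.liftoff_frame)
    opp = d_index if finger == "index" else d_middle
    delay_d, _ = lift_delay_distance(opp, ev.approach_onset_frame, ev.liftoff_frame)
    return LiftDelayRecord(
        delay_force_ms=delay_f, delay_distance_ms=delay_d, opposing_finger=finger
    )
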