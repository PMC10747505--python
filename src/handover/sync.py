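"""Sync-LED pulse codec and cross-stream alignment.

The instrumented handover object flashes an infrared Sync-LED that is
visible both in its own force log (as a logic channel) and in the motion
capture record.  A start signal marks the beginning of a recording; an end
signal additionally carries the object ID (3 bits) and the recording
number (7 bits).  Decoding both streams gives an exact frame offset
between the object clock and the motion-capture clock.

Timing (at the common 100 Hz clock, 10 ms per frame):

* start signal: 200 ms ON, 120 ms OFF, 60 ms ON  (20 / 12 / 6 frames)
* end signal:   10 bits, most significant bit first, object ID first;
  bit 1 = 60 ms ON + 20 ms OFF (6 + 2 frames),
  bit 0 = 30 ms ON + 20 ms OFF (3 + 2 frames).

The two signals share no run-length pattern: a start can never parse as a
bit sequence and vice versa, which is what makes the coding robust against
LED drop-outs compared with a permanent gating signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np

FRAME_RATE_HZ = 100
MS_PER_FRAME = 1000 // FRAME_RATE_HZ

# nominal segment lengths in frames
START_ON_A = 20
START_OFF = 12
START_ON_B = 6
BIT1_ON = 6
BIT0_ON = 3
BIT_OFF = 2

OBJECT_ID_BITS = 3
RECORDING_BITS = 7

#: minimum idle (OFF) run separating two messages
MESSAGE_GAP_FRAMES = 5


class SyncDecodeError(ValueError):
    """Raised when a required sync message cannot be recovered."""


@dataclass(frozen=True)
class PulseTrain:
    """A binary LED state sequence sampled at the mocap/force clock."""

    states: np.ndarray
    frame_rate: int = FRAME_RATE_HZ

    def __post_init__(self) -> None:
        states = np.asarray(self.states)
        if states.size == 0:
            raise ValueError("PulseTrain must be nonempty")
        if not np.isin(states, (0, 1)).all():
            raise ValueError("PulseTrain states must be binary 0/1")
        if self.frame_rate != FRAME_RATE_HZ:
            raise ValueError(f"frame_rate must be {FRAME_RATE_HZ} Hz")
        object.__setattr__(self, "states", states.astype(np.uint8))

    def __len__(self) -> int:
        return int(self.states.size)

    def concat(self, other: "PulseTrain") -> "PulseTrain":
        return PulseTrain(np.concatenate([self.states, other.states]))


@dataclass(frozen=True)
class SyncMessage:
    """A decoded start or end event.

    Start messages carry no payload; end messages carry the 3-bit object
    ID and the 7-bit recording number.  ``onset_frame`` is the frame of
    the first ON sample of the message in its own stream.
    """

    kind: Literal["start", "end"]
    onset_frame: int
    object_id: int | None = None
    recording_number: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "start":
            if self.object_id is not None or self.recording_number is not None:
                raise ValueError("start messages carry no payload")
        elif self.kind == "end":
            if not (0 <= int(self.object_id) < 2**OBJECT_ID_BITS):
                raise ValueError(f"object_id {self.object_id} out of 3-bit range")
            if not (0 <= int(self.recording_number) < 2**RECORDING_BITS):
                raise ValueError(
                    f"recording_number {self.recording_number} out of 7-bit range"
                )
        else:
            raise ValueError(f"unknown message kind {self.kind!r}")


def _frames(on: int, off: int) -> np.ndarray:
    return np.concatenate([np.ones(on, np.uint8), np.zeros(off, np.uint8)])


def encode_start() -> PulseTrain:
    """Frame-quantized start signal: 20 ON, 12 OFF, 6 ON."""
    states = np.concatenate(
        [
            np.ones(START_ON_A, np.uint8),
            np.zeros(START_OFF, np.uint8),
            np.ones(START_ON_B, np.uint8),
        ]
    )
    return PulseTrain(states)


def _to_bits(value: int, width: int) -> list[int]:
    return [(value >> (width - 1 - i)) & 1 for i in range(width)]


def encode_end(object_id: int, recording_number: int) -> PulseTrain:
    """End signal: 3 object-ID bits then 7 recording-number bits, MSB first.

    The trailing 2-frame OFF of the last bit belongs to the message.
    """
    if not (0 <= object_id < 2**OBJECT_ID_BITS):
        raise ValueError(f"object_id must be in [0, 7], got {object_id}")
    if not (0 <= recording_number < 2**RECORDING_BITS):
        raise ValueError(
            f"recording_number must be in [0, 127], got {recording_number}"
        )
    bits = _to_bits(object_id, OBJECT_ID_BITS) + _to_bits(
        recording_number, RECORDING_BITS
    )
    chunks = [_frames(BIT1_ON if b else BIT0_ON, BIT_OFF) for b in bits]
    return PulseTrain(np.concatenate(chunks))


# ---------------------------------------------------------------------------
# decoding


def _run_lengths(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode: list of (state, length, start_frame)."""
    edges = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [states.size]])
    return [(int(states[s]), int(e - s), int(s)) for s, e in zip(starts, ends)]


def _classify(length: int, nominals: Sequence[int], tol: int) -> int | None:
    """Nearest nominal length within ``tol`` frames; None if no or an
    ambiguous match (within tolerance of two codes)."""
    hits = [n for n in nominals if abs(length - n) <= tol]
    if len(hits) != 1:
        return None
    return hits[0]


def _try_start(
    runs: list[tuple[int, int, int]], i: int, tol: int
) -> SyncMessage | None:
    if i + 2 >= len(runs):
        return None
    a, b, c = runs[i], runs[i + 1], runs[i + 2]
    if (
        a[0] == 1
        and b[0] == 0
        and c[0] == 1
        and _classify(a[1], [START_ON_A], tol) is not None
        and _classify(b[1], [START_OFF], tol) is not None
        and _classify(c[1], [START_ON_B], tol) is not None
    ):
        # the run after the trailing ON (if any) must be an idle gap
        if i + 3 < len(runs) and runs[i + 3][1] < MESSAGE_GAP_FRAMES - tol:
            return None
        return SyncMessage("start", onset_frame=a[2])
    return None


def _try_end(runs: list[tuple[int, int, int]], i: int, tol: int) -> SyncMessage | None:
    n_bits = OBJECT_ID_BITS + RECORDING_BITS
    bits: list[int] = []
    j = i
    for k in range(n_bits):
        if j >= len(runs) or runs[j][0] != 1:
            return None
        on = _classify(runs[j][1], [BIT0_ON, BIT1_ON], tol)
        if on is None:
            return None
        bits.append(1 if on == BIT1_ON else 0)
        j += 1
        last = k == n_bits - 1
        if j < len(runs):
            if runs[j][0] != 0:
                return None  # two ON runs cannot be adjacent; defensive
            # the final OFF may merge with the idle gap after the message
            ok = runs[j][1] >= BIT_OFF - tol if last else (
                _classify(runs[j][1], [BIT_OFF], tol) is not None
            )
            if not ok:
                return None
            j += 1
        elif not last:
            return None
    object_id = int("".join(map(str, bits[:OBJECT_ID_BITS])), 2)
    recording = int("".join(map(str, bits[OBJECT_ID_BITS:])), 2)
    return SyncMessage(
        "end", onset_frame=runs[i][2], object_id=object_id, recording_number=recording
    )


def decode(train: PulseTrain, jitter_tolerance_frames: int = 1) -> list[SyncMessage]:
    """Decode every start and end message in a pulse train.

    Segments are classified by nearest nominal length within
    ``jitter_tolerance_frames``; a segment within tolerance of two codes
    is ambiguous and the enclosing candidate message is dropped rather
    than guessed.  Unparseable ON runs yield no message.
    """
    tol = int(jitter_tolerance_frames)
    if tol < 0:
        raise ValueError("jitter tolerance must be >= 0")
    runs = _run_lengths(train.states)
    messages: list[SyncMessage] = []
    i = 0
    while i < len(runs):
        if runs[i][0] != 1:
            i += 1
            continue
        msg = _try_start(runs, i, tol)
        if msg is not None:
            messages.append(msg)
            i += 3
            continue
        msg = _try_end(runs, i, tol)
        if msg is not None:
            messages.append(msg)
            i += 2 * (OBJECT_ID_BITS + RECORDING_BITS)
            continue
        i += 1  # unparseable ON run: skip, never guess
    return messages


def align_streams(object_sync: PulseTrain, mocap_led_track: PulseTrain) -> int:
    """Frame offset such that object frame ``f`` maps to mocap frame
    ``f + offset``, from the decoded start onsets of both streams."""
    obj_starts = [m for m in decode(object_sync) if m.kind == "start"]
    mocap_starts = [m for m in decode(mocap_led_track) if m.kind == "start"]
    if not obj_starts:
        raise SyncDecodeError("no start message decodable in the object stream")
    if not mocap_starts:
        raise SyncDecodeError("no start message decodable in the mocap stream")
    return mocap_starts[0].onset_frame - obj_starts[0].onset_frame
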