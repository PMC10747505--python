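"""On-disk trial formats: force CSV, marker TSV, metadata JSON.

A trial on disk is a directory with three files:

* ``forces.csv`` — comma-separated, header row; ``frame`` column first,
  then the twelve sensor channels (``g_s1_fx`` ... ``r_s2_fz``) and the
  binary ``sync_led`` track.  Always exactly 10,000 rows: recordings
  stopped before 100 s are zero-padded, mirroring the acquisition
  firmware.
* ``markers.tsv`` — wide tab-separated marker file on the *mocap* clock:
  ``frame``, ``sync_led``, then ``<label>_x/_y/_z`` per marker (mm).
  Missing samples (marker gaps) are empty fields / NaN.
* ``meta.json`` — object_id, recording_number, size, weight_g, ids.

Loading re-aligns the two clocks from the decoded Sync-LED start pulses
and validates the decoded end-signal payload against the metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sync import PulseTrain, SyncDecodeError, align_streams, decode
from .synth import FORCE_CHANNELS, MARKER_LABELS, TrialRecording

FORCE_LOG_ROWS = 10_000
MAX_GAP_INTERP_FRAMES = 10  # 100 ms


class TrialIntegrityError(ValueError):
    """Metadata and decoded sync payload disagree, or alignment failed."""


@dataclass(frozen=True)
class ForceLog:
    """In-memory image of a force CSV: padded samples plus stop frame."""

    samples: pd.DataFrame  # FORCE_LOG_ROWS rows: frame, channels, sync_led
    stop_frame: int


def save_force_log(samples: pd.DataFrame, stop_frame: int, path: str | Path) -> None:
    """Write a force log, zero-padded to exactly 10,000 rows.

    ``samples`` holds the real measurements (first ``stop_frame`` rows
    used; channel columns plus ``sync_led``).  Rows beyond ``stop_frame``
    are written as zeros.
    """
    if stop_frame > FORCE_LOG_ROWS:
        raise ValueError(
            f"stop_frame {stop_frame} exceeds the {FORCE_LOG_ROWS}-sample log"
        )
    cols = [c for c in samples.columns if c != "frame"]
    out = pd.DataFrame(0.0, index=range(FORCE_LOG_ROWS), columns=cols)
    out.iloc[:stop_frame] = samples[cols].iloc[:stop_frame].to_numpy()
    out["sync_led"] = out["sync_led"].astype(int)
    out.insert(0, "frame", np.arange(FORCE_LOG_ROWS))
    out.to_csv(path, index=False, float_format="%.6f")


def load_force_log(path: str | Path) -> ForceLog:
    df = pd.read_csv(path)
    if len(df) != FORCE_LOG_ROWS:
        raise ValueError(f"force log must have {FORCE_LOG_ROWS} rows, got {len(df)}")
    data = df.drop(columns=["frame"]).to_numpy()
    nonzero = np.flatnonzero(np.any(data != 0.0, axis=1))
    stop = int(nonzero[-1]) + 1 if nonzero.size else 0
    return ForceLog(samples=df, stop_frame=stop)


def save_markers(
    markers: dict[str, np.ndarray], sync: PulseTrain, path: str | Path,
    mocap_offset: int = 0,
) -> None:
    """Write the wide marker TSV on the mocap clock.

    The aligned (object-clock) trajectories are shifted by
    ``mocap_offset`` frames of pre-roll, during which every marker holds
    its first sample (participants in the rest position) and the Sync-LED
    is dark.
    """
    n = next(iter(markers.values())).shape[0]
    total = n + mocap_offset
    cols: dict[str, np.ndarray] = {"frame": np.arange(total)}
    led = np.zeros(total, np.uint8)
    led[mocap_offset : mocap_offset + len(sync)] = sync.states[:n]
    cols["sync_led"] = led
    for label, xyz in markers.items():
        pre = np.repeat(xyz[:1], mocap_offset, axis=0)
        full = np.vstack([pre, xyz])
        for j, ax in enumerate("xyz"):
            cols[f"{label}_{ax}"] = full[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.4f")


@dataclass(frozen=True)
class MarkerSet:
    """Labeled trajectories with per-label interpolated-gap runs."""

    trajectories: dict[str, np.ndarray]
    sync: PulseTrain
    gap_runs: dict[str, list[tuple[int, int]]]  # label -> [(start, length)]
    long_gap_labels: frozenset[str]


def _fill_gaps(xyz: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]], bool]:
    """Linearly interpolate interior NaN runs of <= MAX_GAP_INTERP_FRAMES.

    Returns the filled array, the list of interpolated (start, length)
    runs, and whether any longer (uninterpolated) gap remains.
    """
    missing = np.isnan(xyz).any(axis=1)
    if not missing.any():
        return xyz, [], False
    runs: list[tuple[int, int]] = []
    long_gap = False
    filled = xyz.copy()
    idx = np.flatnonzero(missing)
    splits = np.flatnonzero(np.diff(idx) > 1)
    for chunk in np.split(idx, splits + 1):
        s, e = int(chunk[0]), int(chunk[-1])
        if s == 0 or e == xyz.shape[0] - 1 or len(chunk) > MAX_GAP_INTERP_FRAMES:
            long_gap = True
            continue
        for j in range(3):
            filled[s : e + 1, j] = np.interp(
                np.arange(s, e + 1), [s - 1, e + 1], xyz[[s - 1, e + 1], j]
            )
        runs.append((s, len(chunk)))
    return filled, runs, long_gap


def load_markers(path: str | Path) -> MarkerSet:
    df = pd.read_csv(path, sep="\t")
    sync = PulseTrain(df["sync_led"].to_numpy().astype(np.uint8))
    labels = sorted({c[:-2] for c in df.columns if c.endswith(("_x", "_y", "_z"))})
    trajectories: dict[str, np.ndarray] = {}
    gap_runs: dict[str, list[tuple[int, int]]] = {}
    long_gaps = set()
    for label in labels:
        xyz = df[[f"{label}_{ax}" for ax in "xyz"]].to_numpy(float)
        filled, runs, long_gap = _fill_gaps(xyz)
        trajectories[label] = filled
        if runs:
            gap_runs[label] = runs
        if long_gap:
            long_gaps.add(label)
    return MarkerSet(trajectories, sync, gap_runs, frozenset(long_gaps))


def save_trial(
    rec: TrialRecording, directory: str | Path, mocap_offset: int | None = None,
) -> Path:
    """Write one trial bundle (forces.csv, markers.tsv, meta.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = rec.stop_frame
    force_df = pd.DataFrame({c: rec.forces[c] for c in FORCE_CHANNELS})
    force_df["sync_led"] = rec.sync.states[:n]
    save_force_log(force_df, stop_frame=n, path=directory / "forces.csv")
    if mocap_offset is None:
        mocap_offset = int(rec.meta.get("mocap_offset", 0))
    save_markers(rec.markers, rec.sync, directory / "markers.tsv", mocap_offset)
    with open(directory / "meta.json", "w") as fh:
        json.dump(rec.meta, fh, indent=1)
    return directory


def load_trial(
    force_path: str | Path,
    marker_path: str | Path,
    meta_path: str | Path,
) -> TrialRecording:
    """Assemble an aligned TrialRecording from the three on-disk files.

    The mocap marker stream is shifted onto the object (force-log) clock
    using the Sync-LED start pulses of both streams; the zero-padded tail
    of the force log is excluded (frames beyond the recording stop never
    enter detection windows).  The decoded end-signal payload must match
    the metadata.
    """
    with open(meta_path) as fh:
        meta = dict(json.load(fh))
    flog = load_force_log(force_path)
    mset = load_markers(marker_path)

    obj_sync = PulseTrain(flog.samples["sync_led"].to_numpy().astype(np.uint8))
    try:
        offset = align_streams(obj_sync, mset.sync)
    except SyncDecodeError as exc:
        raise TrialIntegrityError(f"stream alignment failed: {exc}") from exc

    ends = [m for m in decode(obj_sync) if m.kind == "end"]
    if ends:
        end = ends[-1]
        if end.object_id != int(meta["object_id"]):
            raise TrialIntegrityError(
                f"metadata object_id {meta['object_id']} != decoded {end.object_id}"
            )
        if end.recording_number != int(meta["recording_number"]):
            raise TrialIntegrityError(
                f"metadata recording_number {meta['recording_number']} != "
                f"decoded {end.recording_number}"
            )

    n = flog.stop_frame
    markers: dict[str, np.ndarray] = {}
    for label, xyz in mset.trajectories.items():
        shifted = xyz[offset : offset + n]
        if shifted.shape[0] < n:
            pad = np.repeat(shifted[-1:], n - shifted.shape[0], axis=0)
            shifted = np.vstack([shifted, pad])
        markers[label] = shifted
    gap_flags = {
        label: [(max(0, s - offset), ln) for s, ln in runs]
        for label, runs in mset.gap_runs.items()
    }
    for label in mset.long_gap_labels:
        gap_flags.setdefault(label, []).append((-1, -1))  # sentinel: long gap

    forces = {
        c: flog.samples[c].to_numpy(float)[:n] for c in FORCE_CHANNELS
    }
    sync = PulseTrain(obj_sync.states[:n])
    return TrialRecording(
        markers=markers, forces=forces, sync=sync, meta=meta,
        stop_frame=n, marker_gap_flags=gap_flags,
    )


def load_trial_dir(directory: str | Path) -> TrialRecording:
    d = Path(directory)
    return load_trial(d / "forces.csv", d / "markers.tsv", d / "meta.json")


def validate_trial_dir(directory: str | Path) -> dict:
    """Integrity report for one trial directory (used by the CLI)."""
    report: dict = {"directory": str(directory), "ok": True, "problems": []}
    try:
        rec = load_trial_dir(directory)
    except (TrialIntegrityError, ValueError) as exc:
        report["ok"] = False
        report["problems"].append(str(exc))
        return report
    report["stop_frame"] = rec.stop_frame
    report["n_markers"] = len(rec.markers)
    long_gaps = [k for k, runs in rec.marker_gap_flags.items() if (-1, -1) in runs]
    if long_gaps:
        report["problems"].append(f"long marker gaps: {sorted(long_gaps)}")
    missing = [c for c in FORCE_CHANNELS if c not in rec.forces]
    if missing:
        report["ok"] = False
        report["problems"].append(f"missing force channels: {missing}")
    return report
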