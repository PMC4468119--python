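"""Trajectory cleaning: gap repair, low-pass filtering, repetition segmentation.

Landmark channels are filtered with a second-order Butterworth low-pass at
6 Hz (the conventional cut-off for slow voluntary limb movement sampled at
30 Hz), applied forward-backward by default so that peak timing is not
lag-shifted.  Each coordinate channel is filtered independently; filtering
precedes any angle computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import signal

from .mocap_io import Landmark3D, MotionRecording, SkeletonFrame

if TYPE_CHECKING:  # pragma: no cover
    from .kinematics import AngleTrace

__all__ = [
    "FilterSpec",
    "RepetitionWindow",
    "repair_gaps",
    "lowpass",
    "segment_repetitions",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass design: order, cut-off and sampling rate in Hz."""

    order: int = 2
    cutoff_hz: float = 6.0
    fs_hz: float = 30.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"filter order must be >= 1, got {self.order}")
        if not 0 < self.cutoff_hz < self.fs_hz / 2:
            raise ValueError(
                f"cutoff must lie in (0, fs/2) = (0, {self.fs_hz / 2}) Hz, "
                f"got {self.cutoff_hz}"
            )

    def ba(self) -> tuple[np.ndarray, np.ndarray]:
        return signal.butter(self.order, self.cutoff_hz, fs=self.fs_hz, btype="low")

    @property
    def min_samples(self) -> int:
        # forward-backward filtering pads with 3*(order+1) samples per end
        return 3 * (self.order + 1) + 1


@dataclass(frozen=True)
class RepetitionWindow:
    """Half-open frame range [start_frame, end_frame) holding one repetition."""

    rep_index: int
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise ValueError("repetition window must satisfy start < end")

    def __len__(self) -> int:
        return self.end_frame - self.start_frame


class GapRepairError(ValueError):
    """A landmark cannot be repaired (e.g. never tracked)."""


def _stack(rec: MotionRecording, name: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (n,3) positions and (n,) flags for one landmark across frames."""
    pos = np.full((len(rec.frames), 3), np.nan)
    flags = np.empty(len(rec.frames), dtype=object)
    for i, fr in enumerate(rec.frames):
        if fr.has(name):
            lm = fr.landmark(name)
            pos[i] = lm.position
            flags[i] = lm.tracked
        else:
            flags[i] = "missing"
    return pos, flags


def _rebuild(
    rec: MotionRecording, channels: dict[str, tuple[np.ndarray, np.ndarray]]
) -> MotionRecording:
    frames = []
    for i, fr in enumerate(rec.frames):
        landmarks = []
        for lm in fr.landmarks:
            pos, flags = channels[lm.name]
            landmarks.append(
                Landmark3D(name=lm.name, position=tuple(pos[i]), tracked=flags[i])
            )
        frames.append(SkeletonFrame(t=fr.t, landmarks=tuple(landmarks)))
    return rec.with_frames(frames)


def repair_gaps(rec: MotionRecording, max_gap_frames: int = 5) -> MotionRecording:
    """Linearly interpolate short tracking dropouts.

    Runs of non-``tracked`` samples no longer than ``max_gap_frames`` that
    are flanked by tracked samples are linearly interpolated between the
    flanking positions and re-flagged ``inferred``; longer runs (and runs
    touching the start or end of the recording) are left as ``missing``.

    Raises
    ------
    GapRepairError
        If a landmark has no tracked sample in any frame.
    """
    channels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in rec.landmark_names():
        pos, flags = _stack(rec, name)
        good = np.array([f == "tracked" for f in flags])
        if not good.any():
            raise GapRepairError(f"landmark {name!r} is missing in every frame")
        bad_idx = np.flatnonzero(~good)
        # group consecutive indices into runs
        for run in np.split(bad_idx, np.flatnonzero(np.diff(bad_idx) > 1) + 1):
            if run.size == 0 or run.size > max_gap_frames:
                continue
            lo, hi = run[0] - 1, run[-1] + 1
            if lo < 0 or hi >= len(flags):
                continue  # run touches an edge: no flanking pair
            if flags[lo] != "tracked" or flags[hi] != "tracked":
                continue
            for i in run:
                w = (i - lo) / (hi - lo)
                pos[i] = (1 - w) * pos[lo] + w * pos[hi]
                flags[i] = "inferred"
        channels[name] = (pos, flags)
    return _rebuild(rec, channels)


def lowpass(rec: MotionRecording, spec: FilterSpec | None = None) -> MotionRecording:
    """Low-pass filter every coordinate channel of every landmark.

    Zero-phase mode applies the filter forward and backward
    (:func:`scipy.signal.filtfilt`), squaring the magnitude response and
    cancelling phase lag; ``zero_phase=False`` gives the causal single pass.
    """
    spec = spec or FilterSpec(fs_hz=rec.fs)
    n = len(rec.frames)
    if n < spec.min_samples:
        raise ValueError(
            f"recording too short to filter: {n} frames, need at least "
            f"{spec.min_samples}"
        )
    b, a = spec.ba()
    channels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in rec.landmark_names():
        pos, flags = _stack(rec, name)
        if np.isnan(pos).any():
            raise ValueError(
                f"landmark {name!r} still has missing samples; run repair_gaps "
                "or drop the landmark before filtering"
            )
        if spec.zero_phase:
            out = signal.filtfilt(b, a, pos, axis=0, padlen=spec.min_samples - 1)
        else:
            # start the causal filter from steady state at the first sample
            zi = signal.lfilter_zi(b, a)
            out = np.empty_like(pos)
            for c in range(3):
                out[:, c], _ = signal.lfilter(b, a, pos[:, c], zi=zi * pos[0, c])
        channels[name] = (out, flags)
    return _rebuild(rec, channels)


def segment_repetitions(
    angles: "AngleTrace",
    rest_threshold_deg: float = 20.0,
    min_duration_s: float = 0.5,
) -> list[RepetitionWindow]:
    """Split an angle trace into movement repetitions.

    A repetition is a maximal run of frames with angle >= the rest
    threshold that lasts at least ``min_duration_s``.  Windows are returned
    in time order, indexed from 1; an empty list is a valid result.
    """
    a = np.asarray(angles.angle_deg, dtype=float)
    t = np.asarray(angles.t, dtype=float)
    above = a >= rest_threshold_deg
    windows: list[RepetitionWindow] = []
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return windows
    for run in np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1):
        start, end = int(run[0]), int(run[-1]) + 1
        duration = t[end - 1] - t[start]
        if duration >= min_duration_s:
            windows.append(
                RepetitionWindow(
                    rep_index=len(windows) + 1, start_frame=start, end_frame=end
                )
            )
    return windows
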