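"""End-to-end extraction: recording -> filtered angles -> repetition ROM."""

from __future__ import annotations

from dataclasses import dataclass, field

from .kinematics import (
    AngleTrace,
    ROMRecord,
    angle_trace,
    repetition_peak,
    rom_record,
)
from .mocap_io import MotionRecording
from .preprocess import FilterSpec, lowpass, repair_gaps, segment_repetitions

__all__ = ["ExtractionSettings", "extract_trace", "extract_rom"]


@dataclass(frozen=True)
class ExtractionSettings:
    """Knobs of the recording-to-ROM pipeline (filtering + segmentation)."""

    filter_spec: FilterSpec | None = None  # None -> defaults at the recording fs
    max_gap_frames: int = 5
    rest_threshold_deg: float = 20.0
    min_duration_s: float = 0.5
    plane_mode: str = "anatomical"


def extract_trace(
    rec: MotionRecording,
    method: str = "projection",
    settings: ExtractionSettings = ExtractionSettings(),
) -> AngleTrace:
    """Repair gaps, low-pass filter, and compute the per-frame angle trace."""
    rec = repair_gaps(rec, settings.max_gap_frames)
    spec = settings.filter_spec or FilterSpec(fs_hz=rec.fs)
    rec = lowpass(rec, spec)
    return angle_trace(rec, method=method, plane_mode=settings.plane_mode)


def extract_rom(
    rec: MotionRecording,
    method: str = "projection",
    settings: ExtractionSettings = ExtractionSettings(),
) -> ROMRecord:
    """Full pipeline: preprocessing, angles, repetition peaks, mean ROM.

    Raises ``ValueError`` if no repetition is found in the recording.
    """
    trace = extract_trace(rec, method, settings)
    windows = segment_repetitions(
        trace, settings.rest_threshold_deg, settings.min_duration_s
    )
    if not windows:
        raise ValueError(
            f"no repetitions found in recording {rec.subject_id}/{rec.movement}"
        )
    peaks = [repetition_peak(trace, w) for w in windows]
    return rom_record(peaks, rec.subject_id, rec.movement, method)
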