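"""Shoulder-angle computation from skeletal landmarks.

Two angle definitions are provided:

* **body angle** — the 3D angle between the fitted trunk line (oriented
  caudally, head toward hips) and the fitted arm line (oriented shoulder
  toward hand).  Arm hanging at the side is 0 deg, arm overhead 180 deg.
* **projection angle** — the angle of the arm vector's projection onto the
  movement's anatomical plane (coronal for abduction, sagittal for
  flexion), measured from the caudal trunk direction.  It mimics what a
  goniometer reads off a 2D camera view.

Segment lines are fitted by orthogonal least squares (first principal axis
of the centered landmark scatter), which is rotation-equivariant — a
property coordinate-wise regression lacks and angle computation requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean

import numpy as np

from .mocap_io import MotionRecording, SkeletonFrame
from .preprocess import RepetitionWindow

__all__ = [
    "TRUNK_LANDMARKS",
    "ARM_LANDMARKS",
    "AnatomicalFrame",
    "AngleTrace",
    "RepetitionPeak",
    "ROMRecord",
    "fit_segment_vector",
    "trunk_vector",
    "arm_vector",
    "body_angle",
    "projection_angle",
    "angle_trace",
    "repetition_peak",
    "rom_record",
]

#: Landmarks fitted for the trunk line, cranial to caudal.
TRUNK_LANDMARKS = ("head", "shoulder_center", "spine", "hip_center")

#: Landmarks fitted for the arm line, proximal to distal ({side} in name).
ARM_LANDMARKS = ("shoulder_{side}", "elbow_{side}", "wrist_{side}", "hand_{side}")

_MOVEMENT_PLANE = {"AA": "coronal", "PA": "coronal", "AF": "sagittal", "PF": "sagittal"}


class DegenerateGeometryError(ValueError):
    """Landmark configuration admits no well-defined line or projection."""


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n <= 1e-12:
        raise DegenerateGeometryError(f"zero-norm {what}")
    return v / n


@dataclass(frozen=True)
class AnatomicalFrame:
    """Trunk-anchored right-handed triad used to define projection planes.

    ``longitudinal_up`` points from the hip center toward the shoulder
    center; ``mediolateral`` from the right toward the left shoulder
    (orthogonalized); ``anterior = mediolateral x longitudinal_up``.
    """

    longitudinal_up: np.ndarray
    mediolateral: np.ndarray
    anterior: np.ndarray

    @classmethod
    def from_frame(cls, frame: SkeletonFrame) -> "AnatomicalFrame":
        for name in ("hip_center", "shoulder_center", "shoulder_left", "shoulder_right"):
            if not frame.has(name):
                raise DegenerateGeometryError(
                    f"anatomical frame needs landmark {name!r}"
                )
        up = _unit(
            np.asarray(frame.landmark("shoulder_center").position)
            - np.asarray(frame.landmark("hip_center").position),
            "longitudinal axis",
        )
        ml_raw = np.asarray(frame.landmark("shoulder_left").position) - np.asarray(
            frame.landmark("shoulder_right").position
        )
        ml = _unit(ml_raw - (ml_raw @ up) * up, "mediolateral axis")
        anterior = np.cross(ml, up)
        return cls(longitudinal_up=up, mediolateral=ml, anterior=anterior)

    @classmethod
    def sensor_fixed(cls) -> "AnatomicalFrame":
        """Planes fixed to the sensor axes (+y up, +x subject-left)."""
        return cls(
            longitudinal_up=np.array([0.0, 1.0, 0.0]),
            mediolateral=np.array([1.0, 0.0, 0.0]),
            anterior=np.array([0.0, 0.0, 1.0]),
        )

    @property
    def caudal(self) -> np.ndarray:
        return -self.longitudinal_up

    def plane_axes(self, plane: str) -> tuple[np.ndarray, np.ndarray]:
        if plane == "coronal":
            return self.longitudinal_up, self.mediolateral
        if plane == "sagittal":
            return self.longitudinal_up, self.anterior
        raise ValueError(f"unknown plane {plane!r}")


@dataclass(frozen=True)
class AngleTrace:
    """Per-frame shoulder angle (degrees in [0, 180]) for one recording."""

    method: str  # body | projection
    movement: str
    t: np.ndarray
    angle_deg: np.ndarray

    def __post_init__(self) -> None:
        if len(self.t) != len(self.angle_deg):
            raise ValueError("t and angle_deg must have equal length")


@dataclass(frozen=True)
class RepetitionPeak:
    """Maximal angle of one repetition, averaged over 3 frames at the peak."""

    rep_index: int
    peak_deg: float
    peak_frame: int


@dataclass(frozen=True)
class ROMRecord:
    """Per-subject, per-movement range of motion: mean of repetition peaks.

    Records with fewer than 3 repetitions are kept but flagged excludable
    (``complete`` is False); cohort analyses drop them.
    """

    subject_id: str
    movement: str
    method: str
    rom_deg: float
    n_reps: int

    @property
    def complete(self) -> bool:
        return self.n_reps >= 3


# ---------------------------------------------------------------------------
# segment vectors


def fit_segment_vector(points, orientation_hint) -> np.ndarray:
    """Orthogonal least-squares line direction through 3D points.

    Returns the first principal axis of the centered point scatter (unit
    vector), sign-chosen so its dot product with ``orientation_hint`` is
    non-negative.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise DegenerateGeometryError("need at least 2 points of dimension 3")
    centered = pts - pts.mean(axis=0)
    if not np.isfinite(centered).all():
        raise DegenerateGeometryError("non-finite coordinates in line fit")
    if np.allclose(centered, 0.0, atol=1e-12):
        raise DegenerateGeometryError("all points coincident; no line direction")
    # right singular vector of the largest singular value
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if direction @ np.asarray(orientation_hint, dtype=float) < 0:
        direction = -direction
    return direction


def _positions(frame: SkeletonFrame, names) -> np.ndarray:
    missing = [n for n in names if not frame.has(n) or frame.landmark(n).tracked == "missing"]
    if missing:
        raise DegenerateGeometryError(f"missing landmarks: {missing}")
    return np.array([frame.landmark(n).position for n in names], dtype=float)


def trunk_vector(frame: SkeletonFrame) -> np.ndarray:
    """Caudal trunk direction: line fit through head/shoulder/spine/hip."""
    pts = _positions(frame, TRUNK_LANDMARKS)
    hint = pts[-1] - pts[0]  # head -> hip_center
    return fit_segment_vector(pts, hint)


def arm_vector(frame: SkeletonFrame, side: str) -> np.ndarray:
    """Proximal-to-distal arm direction: line fit through the arm landmarks.

    The hand landmark participates only when present and tracked.
    """
    names = [n.format(side=side) for n in ARM_LANDMARKS]
    hand = names[-1]
    if not frame.has(hand) or frame.landmark(hand).tracked == "missing":
        names = names[:-1]
    pts = _positions(frame, names)
    hint = pts[-1] - pts[0]  # shoulder -> most distal
    return fit_segment_vector(pts, hint)


# ---------------------------------------------------------------------------
# angles


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    cosang = float(np.clip(_unit(u) @ _unit(v), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def body_angle(arm: np.ndarray, trunk_caudal: np.ndarray) -> float:
    """3D angle (degrees) between the arm vector and the caudal trunk line."""
    return _angle_between(arm, trunk_caudal)


def projection_angle(
    arm: np.ndarray, frame: AnatomicalFrame, movement_plane: str
) -> float:
    """Angle of the arm's in-plane projection, from the caudal direction.

    ``movement_plane`` is ``coronal`` (abduction) or ``sagittal`` (flexion).
    Raises :class:`DegenerateGeometryError` when the arm is essentially
    orthogonal to the plane (projected norm <= 1e-6).
    """
    arm = _unit(arm, "arm vector")
    e1, e2 = frame.plane_axes(movement_plane)
    proj = (arm @ e1) * e1 + (arm @ e2) * e2
    if np.linalg.norm(proj) <= 1e-6:
        raise DegenerateGeometryError(
            f"arm vector nearly orthogonal to the {movement_plane} plane"
        )
    return _angle_between(proj, frame.caudal)


def angle_trace(
    rec: MotionRecording,
    method: str = "projection",
    plane_mode: str = "anatomical",
) -> AngleTrace:
    """Per-frame shoulder angle for a preprocessed recording.

    The projection method uses the movement's plane (abduction -> coronal,
    flexion -> sagittal) with the anatomical frame rebuilt every frame from
    the trunk landmarks; ``plane_mode='sensor_fixed'`` uses sensor axes
    instead.  The body method needs no plane.
    """
    if method not in ("body", "projection"):
        raise ValueError(f"unknown method {method!r}")
    plane = _MOVEMENT_PLANE[rec.movement]
    t = np.array([fr.t for fr in rec.frames])
    angles = np.empty(len(rec.frames))
    for i, fr in enumerate(rec.frames):
        try:
            arm = arm_vector(fr, rec.side)
            if method == "body":
                angles[i] = body_angle(arm, trunk_vector(fr))
            else:
                anat = (
                    AnatomicalFrame.from_frame(fr)
                    if plane_mode == "anatomical"
                    else AnatomicalFrame.sensor_fixed()
                )
                angles[i] = projection_angle(arm, anat, plane)
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(f"frame {i} (t={fr.t:.3f}s): {exc}") from exc
    return AngleTrace(method=method, movement=rec.movement, t=t, angle_deg=angles)


def repetition_peak(trace: AngleTrace, window: RepetitionWindow) -> RepetitionPeak:
    """Peak angle of a repetition, averaged over 3 consecutive frames.

    The 3-frame window is centered on the maximal frame; at a window
    boundary it is shifted inward to stay inside the repetition.  Ties are
    broken by the earliest maximal frame.
    """
    if len(window) < 3:
        raise ValueError("repetition window must span at least 3 frames")
    seg = np.asarray(trace.angle_deg[window.start_frame : window.end_frame])
    local_peak = int(np.argmax(seg))  # argmax takes the earliest maximum
    center = min(max(local_peak, 1), len(seg) - 2)
    peak_deg = fmean(seg[center - 1 : center + 2])
    return RepetitionPeak(
        rep_index=window.rep_index,
        peak_deg=float(peak_deg),
        peak_frame=window.start_frame + local_peak,
    )


def rom_record(
    peaks: list[RepetitionPeak], subject_id: str, movement: str, method: str
) -> ROMRecord:
    """Range of motion: arithmetic mean of repetition peak angles."""
    if not peaks:
        raise ValueError("cannot compute ROM from zero repetitions")
    return ROMRecord(
        subject_id=subject_id,
        movement=movement,
        method=method,
        rom_deg=fmean(p.peak_deg for p in peaks),
        n_reps=len(peaks),
    )
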