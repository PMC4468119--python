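"""Reading and writing skeletal-landmark recordings and goniometry tables.

The recording data model mirrors what a Kinect-class depth sensor streams:
per-frame named 3D landmarks (meters, sensor frame) at a nominal 30 Hz,
each with a tracking-confidence flag.  Coordinates are stored exactly as
captured; anatomical-frame logic lives in :mod:`romscreen.kinematics`.

Formats
-------
* long CSV  — one row per frame per landmark, columns
  ``t_s,landmark,x_m,y_m,z_m,tracked``; recording metadata as leading
  ``# key=value`` comment lines.
* JSON      — ``{subject_id, movement, side, sensor_placement, fs,
  frames: [{t, landmarks: {name: [x, y, z, flag]}}]}``.
* TRC       — write-only marker-trajectory export for third-party
  biomechanics tools.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DEFAULT_VOCABULARY",
    "MOVEMENTS",
    "TRACK_FLAGS",
    "SchemaError",
    "Landmark3D",
    "SkeletonFrame",
    "MotionRecording",
    "GoniometryRecord",
    "read_recording",
    "write_recording",
    "read_goniometry",
    "write_goniometry",
]

#: Kinect-v1 upper-body landmark vocabulary (default; overridable per call).
DEFAULT_VOCABULARY = frozenset(
    {
        "head",
        "shoulder_center",
        "spine",
        "hip_center",
        "shoulder_left",
        "shoulder_right",
        "elbow_left",
        "elbow_right",
        "wrist_left",
        "wrist_right",
        "hand_left",
        "hand_right",
        "hip_left",
        "hip_right",
    }
)

#: The four recorded movement types: active/passive abduction and flexion.
MOVEMENTS = ("AA", "PA", "AF", "PF")

TRACK_FLAGS = ("tracked", "inferred", "missing")

SIDES = ("left", "right")
PLACEMENTS = ("frontal", "lateral")


class SchemaError(ValueError):
    """An input file violates the recording or goniometry schema."""


@dataclass(frozen=True)
class Landmark3D:
    """One named landmark in one frame: position in meters, sensor frame."""

    name: str
    position: tuple[float, float, float]
    tracked: str = "tracked"

    def validate(self, vocabulary: frozenset[str] = DEFAULT_VOCABULARY) -> None:
        if self.name not in vocabulary:
            raise SchemaError(f"unknown landmark name {self.name!r}")
        if self.tracked not in TRACK_FLAGS:
            raise SchemaError(
                f"landmark {self.name!r}: bad tracking flag {self.tracked!r}"
            )
        if self.tracked != "missing" and not all(
            math.isfinite(c) for c in self.position
        ):
            raise SchemaError(
                f"landmark {self.name!r}: non-finite position with flag "
                f"{self.tracked!r}"
            )


@dataclass(frozen=True)
class SkeletonFrame:
    """All landmarks captured at one timestamp (seconds, monotone in a trial)."""

    t: float
    landmarks: tuple[Landmark3D, ...]

    def landmark(self, name: str) -> Landmark3D:
        for lm in self.landmarks:
            if lm.name == name:
                return lm
        raise KeyError(name)

    def has(self, name: str) -> bool:
        return any(lm.name == name for lm in self.landmarks)

    def validate(self, vocabulary: frozenset[str] = DEFAULT_VOCABULARY) -> None:
        if self.t < 0:
            raise SchemaError(f"negative timestamp {self.t}")
        names = [lm.name for lm in self.landmarks]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate landmark names in frame t={self.t}: {dupes}")
        for lm in self.landmarks:
            lm.validate(vocabulary)


@dataclass
class MotionRecording:
    """One recorded movement trial: ordered skeleton frames plus metadata.

    ``side`` is the surgical (measured) side; ``sensor_placement`` records
    whether the sensor stood in front of the subject or to the side.
    """

    subject_id: str
    movement: str
    frames: list[SkeletonFrame] = field(default_factory=list)
    side: str = "right"
    sensor_placement: str = "frontal"
    fs: float = 30.0

    def validate(
        self,
        vocabulary: frozenset[str] = DEFAULT_VOCABULARY,
        check_timing: bool = False,
    ) -> None:
        if self.movement not in MOVEMENTS:
            raise SchemaError(f"unknown movement code {self.movement!r}")
        if self.side not in SIDES:
            raise SchemaError(f"unknown side {self.side!r}")
        if self.sensor_placement not in PLACEMENTS:
            raise SchemaError(f"unknown sensor placement {self.sensor_placement!r}")
        if not self.fs > 0:
            raise SchemaError(f"sampling rate must be positive, got {self.fs}")
        times = [f.t for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise SchemaError("frame timestamps not strictly increasing")
        for f in self.frames:
            f.validate(vocabulary)
        if check_timing and len(times) > 1:
            dt = 1.0 / self.fs
            for a, b in zip(times, times[1:]):
                if abs((b - a) - dt) > 0.5 * dt:
                    raise SchemaError(
                        f"inter-frame interval {b - a:.4f} s deviates more than "
                        f"50% from 1/fs = {dt:.4f} s"
                    )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def landmark_names(self) -> list[str]:
        names: list[str] = []
        for f in self.frames:
            for lm in f.landmarks:
                if lm.name not in names:
                    names.append(lm.name)
        return names

    def with_frames(self, frames: Sequence[SkeletonFrame]) -> "MotionRecording":
        return replace(self, frames=list(frames))


@dataclass(frozen=True)
class GoniometryRecord:
    """One manual goniometric angle: subject, movement, repetition, degrees."""

    subject_id: str
    movement: str
    rep_index: int
    angle_deg: float

    def validate(self) -> None:
        if self.movement not in MOVEMENTS:
            raise SchemaError(f"unknown movement code {self.movement!r}")
        if self.rep_index < 1:
            raise SchemaError(f"rep_index must be >= 1, got {self.rep_index}")
        if not math.isfinite(self.angle_deg) or not 0.0 <= self.angle_deg <= 200.0:
            raise SchemaError(
                f"angle_deg must be finite and within [0, 200], got {self.angle_deg}"
            )


# ---------------------------------------------------------------------------
# recording I/O

_CSV_COLUMNS = ["t_s", "landmark", "x_m", "y_m", "z_m", "tracked"]
_META_KEYS = ("subject_id", "movement", "side", "sensor_placement", "fs")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower().lstrip(".")
    return suffix if suffix in {"csv", "json", "trc"} else "csv"


def read_recording(
    path: str | Path,
    format: str | None = None,
    vocabulary: frozenset[str] = DEFAULT_VOCABULARY,
) -> MotionRecording:
    """Read and validate a recording from long CSV or JSON.

    Raises :class:`SchemaError` with the offending row/field on any
    schema violation (unknown landmark, duplicate (t, landmark), bad flag,
    non-monotone time, empty file).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        rec = _read_csv(path)
    elif fmt == "json":
        rec = _read_json(path)
    else:
        raise ValueError(f"unsupported read format {fmt!r}")
    if not rec.frames:
        raise SchemaError(f"{path}: recording contains no frames")
    rec.validate(vocabulary)
    return rec


def _parse_float(text: str, where: str) -> float:
    if text == "" or text.lower() in {"nan", "na"}:
        return math.nan
    try:
        return float(text)
    except ValueError as exc:
        raise SchemaError(f"{where}: cannot parse number {text!r}") from exc


def _read_csv(path: Path) -> MotionRecording:
    meta: dict[str, str] = {}
    rows: list[tuple[float, Landmark3D]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        header: list[str] | None = None
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            cells = next(csv.reader([line]))
            if header is None:
                header = [c.strip() for c in cells]
                if header != _CSV_COLUMNS:
                    raise SchemaError(
                        f"{path}:{i}: expected header {','.join(_CSV_COLUMNS)}, "
                        f"got {','.join(header)}"
                    )
                continue
            if len(cells) != len(_CSV_COLUMNS):
                raise SchemaError(f"{path}:{i}: expected {len(_CSV_COLUMNS)} fields")
            where = f"{path}:{i}"
            t = _parse_float(cells[0], where)
            lm = Landmark3D(
                name=cells[1],
                position=(
                    _parse_float(cells[2], where),
                    _parse_float(cells[3], where),
                    _parse_float(cells[4], where),
                ),
                tracked=cells[5],
            )
            rows.append((t, lm))
    if header is None:
        raise SchemaError(f"{path}: empty file")

    frames: list[SkeletonFrame] = []
    by_t: dict[float, list[Landmark3D]] = {}
    order: list[float] = []
    for t, lm in rows:
        if t not in by_t:
            by_t[t] = []
            order.append(t)
        if any(existing.name == lm.name for existing in by_t[t]):
            raise SchemaError(
                f"{path}: duplicate landmark {lm.name!r} at t={t}"
            )
        by_t[t].append(lm)
    for t in order:
        frames.append(SkeletonFrame(t=t, landmarks=tuple(by_t[t])))

    return MotionRecording(
        subject_id=meta.get("subject_id", "unknown"),
        movement=meta.get("movement", "AA"),
        side=meta.get("side", "right"),
        sensor_placement=meta.get("sensor_placement", "frontal"),
        fs=float(meta.get("fs", 30.0)),
        frames=frames,
    )


def _read_json(path: Path) -> MotionRecording:
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    try:
        frames = []
        for fr in data["frames"]:
            landmarks = tuple(
                Landmark3D(
                    name=name,
                    position=(float(v[0]), float(v[1]), float(v[2])),
                    tracked=str(v[3]),
                )
                for name, v in fr["landmarks"].items()
            )
            frames.append(SkeletonFrame(t=float(fr["t"]), landmarks=landmarks))
        return MotionRecording(
            subject_id=str(data["subject_id"]),
            movement=str(data["movement"]),
            side=str(data.get("side", "right")),
            sensor_placement=str(data.get("sensor_placement", "frontal")),
            fs=float(data.get("fs", 30.0)),
            frames=frames,
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise SchemaError(f"{path}: malformed recording JSON ({exc!r})") from exc


def write_recording(
    rec: MotionRecording, path: str | Path, format: str | None = None
) -> None:
    """Write a recording as long CSV, JSON, or TRC (export only)."""
    if not rec.frames:
        raise ValueError("refusing to write a recording with no frames")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv(rec, path)
    elif fmt == "json":
        _write_json(rec, path)
    elif fmt == "trc":
        _write_trc(rec, path)
    else:
        raise ValueError(f"unsupported write format {fmt!r}")


_NUM_FMT = "{:.9f}"


def _write_csv(rec: MotionRecording, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        for key in _META_KEYS:
            fh.write(f"# {key} = {getattr(rec, key)}\n")
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for fr in rec.frames:
            for lm in fr.landmarks:
                writer.writerow(
                    [
                        _NUM_FMT.format(fr.t),
                        lm.name,
                        *(_NUM_FMT.format(c) for c in lm.position),
                        lm.tracked,
                    ]
                )


def _write_json(rec: MotionRecording, path: Path) -> None:
    data = {
        "subject_id": rec.subject_id,
        "movement": rec.movement,
        "side": rec.side,
        "sensor_placement": rec.sensor_placement,
        "fs": rec.fs,
        "frames": [
            {
                "t": round(fr.t, 9),
                "landmarks": {
                    lm.name: [*(round(c, 9) for c in lm.position), lm.tracked]
                    for lm in fr.landmarks
                },
            }
            for fr in rec.frames
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")


def _write_trc(rec: MotionRecording, path: Path) -> None:
    # Standard marker-trajectory header; missing samples exported as blanks.
    names = rec.landmark_names()
    n_frames = len(rec.frames)
    rate = rec.fs
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(
            f"{rate:g}\t{rate:g}\t{n_frames}\t{len(names)}\tm\t{rate:g}\t1\t{n_frames}\n"
        )
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\n")
        axes = "\t".join(f"X{i}\tY{i}\tZ{i}" for i in range(1, len(names) + 1))
        fh.write(f"\t\t{axes}\n\n")
        for i, fr in enumerate(rec.frames, start=1):
            cells = [str(i), f"{fr.t:.5f}"]
            for name in names:
                if fr.has(name) and fr.landmark(name).tracked != "missing":
                    cells.extend(f"{c:.5f}" for c in fr.landmark(name).position)
                else:
                    cells.extend(["", "", ""])
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# goniometry I/O

_GONIO_COLUMNS = ["subject_id", "movement", "rep_index", "angle_deg"]


def read_goniometry(path: str | Path) -> list[GoniometryRecord]:
    """Read a goniometry CSV (``subject_id,movement,rep_index,angle_deg``)."""
    path = Path(path)
    records: list[GoniometryRecord] = []
    seen: set[tuple[str, str, int]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = [c.strip() for c in next(reader)]
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        if header != _GONIO_COLUMNS:
            raise SchemaError(
                f"{path}: expected header {','.join(_GONIO_COLUMNS)}, "
                f"got {','.join(header)}"
            )
        for i, cells in enumerate(reader, start=2):
            if not cells:
                continue
            if len(cells) != 4:
                raise SchemaError(f"{path}:{i}: expected 4 fields")
            where = f"{path}:{i}"
            try:
                rep = int(cells[2])
            except ValueError as exc:
                raise SchemaError(f"{where}: bad rep_index {cells[2]!r}") from exc
            rec = GoniometryRecord(
                subject_id=cells[0],
                movement=cells[1],
                rep_index=rep,
                angle_deg=_parse_float(cells[3], where),
            )
            try:
                rec.validate()
            except SchemaError as exc:
                raise SchemaError(f"{where}: {exc}") from None
            key = (rec.subject_id, rec.movement, rec.rep_index)
            if key in seen:
                raise SchemaError(f"{where}: duplicate repetition {key}")
            seen.add(key)
            records.append(rec)
    return records


def write_goniometry(records: Iterable[GoniometryRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_GONIO_COLUMNS)
        for r in records:
            writer.writerow([r.subject_id, r.movement, r.rep_index, f"{r.angle_deg:.6f}"])
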