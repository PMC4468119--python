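"""Shared fixtures: small hand-built and randomly generated recordings."""

from __future__ import annotations

import numpy as np
import pytest

from romscreen.mocap_io import (
    DEFAULT_VOCABULARY,
    Landmark3D,
    MotionRecording,
    SkeletonFrame,
)


def make_recording(
    positions_per_frame,
    fs: float = 30.0,
    subject_id: str = "s1",
    movement: str = "AA",
    side: str = "right",
) -> MotionRecording:
    """Build a recording from a list of {landmark: (x, y, z) | (xyz, flag)}."""
    frames = []
    for i, frame_positions in enumerate(positions_per_frame):
        landmarks = []
        for name, value in frame_positions.items():
            if len(value) == 2 and isinstance(value[1], str):
                pos, flag = value
            else:
                pos, flag = value, "tracked"
            landmarks.append(Landmark3D(name=name, position=tuple(pos), tracked=flag))
        frames.append(SkeletonFrame(t=i / fs, landmarks=tuple(landmarks)))
    return MotionRecording(
        subject_id=subject_id, movement=movement, side=side, fs=fs, frames=frames
    )


def random_recording(rng: np.random.Generator, n_frames: int = 12) -> MotionRecording:
    """Random-walk positions over the full landmark vocabulary."""
    names = sorted(DEFAULT_VOCABULARY)
    start = rng.uniform(-1, 1, size=(len(names), 3))
    steps = rng.normal(0, 0.02, size=(n_frames, len(names), 3))
    walk = start + np.cumsum(steps, axis=0)
    frames = []
    for i in range(n_frames):
        landmarks = tuple(
            Landmark3D(name=name, position=tuple(walk[i, j]))
            for j, name in enumerate(names)
        )
        frames.append(SkeletonFrame(t=i / 30.0, landmarks=landmarks))
    return MotionRecording(
        subject_id="rand", movement="AF", side="left", fs=30.0, frames=frames
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_recording() -> MotionRecording:
    """2 frames x 4 landmarks, hand-written."""
    return make_recording(
        [
            {
                "shoulder_right": (0.0, 1.5, 0.0),
                "elbow_right": (0.0, 1.2, 0.0),
                "wrist_right": (0.0, 0.95, 0.0),
                "hand_right": (0.0, 0.85, 0.0),
            },
            {
                "shoulder_right": (0.0, 1.5, 0.0),
                "elbow_right": (0.1, 1.21, 0.0),
                "wrist_right": (0.2, 0.99, 0.0),
                "hand_right": (0.25, 0.9, 0.0),
            },
        ]
    )
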