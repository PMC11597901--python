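"""Domain containers shared by every stage of the pipeline.

Conventions fixed here and relied on everywhere else:

* World frame: X = walking direction, Y = mediolateral (left positive),
  Z = vertical up.  All signed flexion rules reference this frame.
* Units: metres, seconds, degrees, newtons.
* Missing keypoint detections are encoded as NaN positions with confidence
  0 — never as zero coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: The 17-keypoint COCO skeleton, in canonical order.
COCO_KEYPOINTS: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

#: name -> index into the keypoint axis
KEYPOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(COCO_KEYPOINTS)}

_JOINTS = ("hip", "knee")
_SIDES = ("right", "left")


class ValidationError(ValueError):
    """Raised when a container invariant or file-format contract is violated."""


def _as_float_array(x, name: str, shape: tuple | None = None) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if shape is not None and arr.shape != shape:
        raise ValidationError(f"{name}: expected shape {shape}, got {arr.shape}")
    return arr


def _check_uniform_timestamps(t: np.ndarray, rate: float, what: str, rtol: float = 1e-3) -> None:
    if t.ndim != 1:
        raise ValidationError(f"{what}: timestamps must be 1-D")
    if np.any(~np.isfinite(t)):
        raise ValidationError(f"{what}: timestamps contain non-finite values")
    if t.size >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError(f"{what}: timestamps must be strictly increasing")
        expected = 1.0 / rate
        if np.any(np.abs(dt - expected) > rtol * expected + 1e-9):
            raise ValidationError(
                f"{what}: timestamp spacing deviates from 1/{rate} Hz beyond tolerance"
            )


@dataclass
class KeypointFrameSet:
    """One camera's 3-D COCO-17 keypoint observations over time.

    Parameters
    ----------
    camera_id
        Label of the originating camera.
    sample_rate
        Frames per second (markerless default 30 Hz).
    timestamps
        Seconds from trial start, strictly increasing, uniformly spaced.
    positions
        ``(n_frames, 17, 3)`` array of x/y/z in metres.  An absent detection
        is a NaN triple.
    confidence
        ``(n_frames, 17)`` detector confidences in [0, 1]; 0 where absent.
    frame_of_reference
        ``"camera"`` or ``"world"``.
    """

    camera_id: str
    sample_rate: float
    timestamps: np.ndarray
    positions: np.ndarray
    confidence: np.ndarray
    frame_of_reference: str = "camera"

    def __post_init__(self) -> None:
        self.timestamps = _as_float_array(self.timestamps, "timestamps")
        n = self.timestamps.size
        self.positions = _as_float_array(self.positions, "positions", (n, 17, 3))
        self.confidence = _as_float_array(self.confidence, "confidence", (n, 17))
        if self.frame_of_reference not in ("camera", "world"):
            raise ValidationError(
                f"frame_of_reference must be 'camera' or 'world', got {self.frame_of_reference!r}"
            )
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        _check_uniform_timestamps(self.timestamps, self.sample_rate, "KeypointFrameSet")
        if np.any(np.isnan(self.confidence)):
            raise ValidationError("confidence must not contain NaN")
        if np.any((self.confidence < 0) | (self.confidence > 1)):
            raise ValidationError("confidence must lie in [0, 1]")
        # a keypoint is either fully present (finite triple) or fully absent
        finite = np.isfinite(self.positions)
        partial = finite.any(axis=-1) & ~finite.all(axis=-1)
        if np.any(partial):
            raise ValidationError("keypoint positions must be fully present or fully NaN")

    @property
    def n_frames(self) -> int:
        return self.timestamps.size

    def present(self) -> np.ndarray:
        """Boolean ``(n_frames, 17)`` mask of available detections."""
        return np.isfinite(self.positions).all(axis=-1)

    def keypoint(self, name: str) -> np.ndarray:
        """Trajectory ``(n_frames, 3)`` of one named keypoint."""
        return self.positions[:, KEYPOINT_INDEX[name], :]


@dataclass
class CameraExtrinsics:
    """Rigid camera→world transform: ``p_world = R @ p_cam + t``."""

    camera_id: str
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = _as_float_array(self.rotation, "rotation", (3, 3))
        self.translation = _as_float_array(self.translation, "translation", (3,))
        if np.any(~np.isfinite(self.rotation)) or np.any(~np.isfinite(self.translation)):
            raise ValidationError("extrinsics must be finite")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValidationError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValidationError("rotation must be proper (det +1)")

    @property
    def position(self) -> np.ndarray:
        """Camera optical centre in world coordinates."""
        return self.translation


@dataclass
class AngleWaveform:
    """A uniformly sampled joint-angle time series, degrees, flexion positive."""

    joint: str
    side: str
    sample_rate: float
    values: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        if self.joint not in _JOINTS:
            raise ValidationError(f"joint must be one of {_JOINTS}, got {self.joint!r}")
        if self.side not in _SIDES:
            raise ValidationError(f"side must be one of {_SIDES}, got {self.side!r}")
        self.values = _as_float_array(self.values, "values")
        self.timestamps = _as_float_array(self.timestamps, "timestamps")
        if self.values.shape != self.timestamps.shape:
            raise ValidationError("values and timestamps must have equal length")
        if np.any(~np.isfinite(self.values)):
            raise ValidationError("angle values must be finite")
        _check_uniform_timestamps(self.timestamps, self.sample_rate, "AngleWaveform")


@dataclass
class GrfSeries:
    """Vertical ground-reaction-force series from a force plate."""

    sample_rate: float
    vertical_force: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.vertical_force = _as_float_array(self.vertical_force, "vertical_force")
        self.timestamps = _as_float_array(self.timestamps, "timestamps")
        if self.vertical_force.shape != self.timestamps.shape:
            raise ValidationError("force and timestamps must have equal length")
        if np.any(~np.isfinite(self.vertical_force)):
            raise ValidationError("forces must be finite")
        if np.any(self.vertical_force < 0):
            raise ValidationError("vertical force must be non-negative")
        _check_uniform_timestamps(self.timestamps, self.sample_rate, "GrfSeries")


@dataclass
class TrialRecord:
    """All streams of one participant × session × speed trial."""

    participant_id: str
    session: int
    speed: float
    markerless: Mapping[str, KeypointFrameSet] = field(default_factory=dict)
    reference: Mapping[str, AngleWaveform] = field(default_factory=dict)
    grf: GrfSeries | None = None

    def __post_init__(self) -> None:
        if self.session not in (1, 2):
            raise ValidationError(f"session must be 1 or 2, got {self.session}")
        if self.speed <= 0:
            raise ValidationError("speed must be positive")


@dataclass
class StatsConfig:
    """Tunables of the statistics and filtering stages.

    ``mdc_convention`` selects the SEM→MDC factor: ``"z_over_sqrt2"``
    (1.96/√2 ≈ 1.386, the arithmetic several published gait-reliability
    tables follow) or ``"z_times_sqrt2"`` (the conventional
    MDC95 = 1.96·√2·SEM).
    """

    z_coverage: float = 1.96
    mdc_convention: str = "z_over_sqrt2"
    normalized_points: int = 101
    filter_order: int = 4
    filter_cutoff: float = 6.0

    def __post_init__(self) -> None:
        if self.z_coverage <= 0:
            raise ValidationError("z_coverage must be positive")
        if self.mdc_convention not in ("z_over_sqrt2", "z_times_sqrt2"):
            raise ValidationError(f"unknown mdc_convention {self.mdc_convention!r}")
        if self.normalized_points < 2:
            raise ValidationError("normalized_points must be >= 2")
        if self.filter_order < 1:
            raise ValidationError("filter_order must be >= 1")
        if self.filter_cutoff <= 0:
            raise ValidationError("filter_cutoff must be positive")
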