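"""From per-camera keypoint streams to signed hip/knee flexion waveforms.

The angle convention: hip flexion is the signed sagittal-plane angle between
the trunk vector (hip→shoulder) and the thigh vector (hip→knee), measured as
180° minus the included angle so that a straight standing pose reads 0°;
knee flexion likewise from the thigh (knee→hip) and shank (knee→ankle)
vectors.  The sign comes from the cross-product component along a caller
supplied sagittal normal, chosen per joint and side so that anatomical
flexion is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from gaitmmc.types import (
    COCO_KEYPOINTS,
    KEYPOINT_INDEX,
    AngleWaveform,
    CameraExtrinsics,
    KeypointFrameSet,
    StatsConfig,
    ValidationError,
)

#: mediolateral world axis (left positive); sagittal planes are orthogonal to it
MEDIOLATERAL_AXIS = np.array([0.0, 1.0, 0.0])


@dataclass
class FusedSkeletonSeries:
    """A single unified keypoint stream after multi-camera fusion."""

    sample_rate: float
    timestamps: np.ndarray
    positions: np.ndarray  # (n, 17, 3), NaN where no camera survived
    weights: np.ndarray  # (n, 17, n_cameras) fusion weights, rows sum to 1 or 0
    camera_ids: tuple[str, ...]

    def keypoint(self, name: str) -> np.ndarray:
        return self.positions[:, KEYPOINT_INDEX[name], :]


def to_world(frames: KeypointFrameSet, extrinsics: CameraExtrinsics) -> KeypointFrameSet:
    """Apply the rigid camera→world transform ``p_world = R p_cam + t``."""
    if frames.frame_of_reference != "camera":
        raise ValidationError("frames are already in the world frame")
    pos = frames.positions @ extrinsics.rotation.T + extrinsics.translation
    return KeypointFrameSet(
        camera_id=frames.camera_id,
        sample_rate=frames.sample_rate,
        timestamps=frames.timestamps.copy(),
        positions=pos,
        confidence=frames.confidence.copy(),
        frame_of_reference="world",
    )


def fuse_keypoints(
    world_frames: list[KeypointFrameSet],
    gate_distance: float = 0.15,
) -> FusedSkeletonSeries:
    """Merge per-camera world-frame streams into one skeleton series.

    Per keypoint per frame: cameras whose observation lies farther than
    ``gate_distance`` from the per-keypoint median position are excluded,
    and the survivors are combined by confidence-weighted mean.  A keypoint
    is absent when no camera survives.
    """
    if not world_frames:
        raise ValidationError("no camera streams to fuse")
    for fs in world_frames:
        if fs.frame_of_reference != "world":
            raise ValidationError(f"camera {fs.camera_id!r}: fusion requires world-frame input")
    rates = {round(fs.sample_rate, 6) for fs in world_frames}
    if len(rates) > 1:
        raise ValidationError(f"cameras disagree on sample rate: {sorted(rates)}")
    rate = world_frames[0].sample_rate
    half_frame = 0.5 / rate

    t0 = max(fs.timestamps[0] for fs in world_frames)
    t1 = min(fs.timestamps[-1] for fs in world_frames)
    if t1 < t0:
        raise ValidationError("camera streams have no overlapping time support")

    ref = world_frames[0]
    keep = (ref.timestamps >= t0 - half_frame) & (ref.timestamps <= t1 + half_frame)
    t = ref.timestamps[keep]
    n = t.size
    n_cam = len(world_frames)

    stacked = np.full((n_cam, n, 17, 3), np.nan)
    confs = np.zeros((n_cam, n, 17))
    for c, fs in enumerate(world_frames):
        idx = np.rint((t - fs.timestamps[0]) * rate).astype(int)
        if np.any(idx < 0) or np.any(idx >= fs.n_frames):
            raise ValidationError(f"camera {fs.camera_id!r}: timestamps not aligned")
        if np.any(np.abs(fs.timestamps[idx] - t) > half_frame):
            raise ValidationError(
                f"camera {fs.camera_id!r}: timestamps misaligned beyond half a frame"
            )
        stacked[c] = fs.positions[idx]
        confs[c] = fs.confidence[idx]

    present = np.isfinite(stacked).all(axis=-1)  # (n_cam, n, 17)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN keypoint slices
        median = np.nanmedian(stacked, axis=0)  # (n, 17, 3)
        dist = np.linalg.norm(stacked - median[None], axis=-1)  # (n_cam, n, 17)
    survives = present & (dist <= gate_distance)
    w = np.where(survives, confs, 0.0)
    wsum = w.sum(axis=0)  # (n, 17)
    # zero-confidence survivors fall back to an unweighted mean
    degenerate = survives.any(axis=0) & (wsum == 0)
    w = np.where(degenerate[None] & survives, 1.0, w)
    wsum = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fused = np.einsum("cnk,cnkd->nkd", w, np.nan_to_num(stacked)) / wsum[..., None]
        weights = np.where(wsum[None] > 0, w / wsum[None], 0.0)
    fused[wsum == 0] = np.nan

    return FusedSkeletonSeries(
        sample_rate=rate,
        timestamps=t,
        positions=fused,
        weights=np.moveaxis(weights, 0, -1),
        camera_ids=tuple(fs.camera_id for fs in world_frames),
    )


def lowpass(values: np.ndarray, fs: float, cutoff: float = 6.0, order: int = 4) -> np.ndarray:
    """Zero-phase (forward–backward) Butterworth low-pass along axis 0."""
    values = np.asarray(values, dtype=float)
    if cutoff >= fs / 2:
        raise ValidationError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2} Hz")
    if values.shape[0] <= 3 * order:
        raise ValidationError("series too short for the requested filter order")
    b, a = butter(order, cutoff, btype="low", fs=fs)
    return filtfilt(b, a, values, axis=0)


def flexion_angle(
    a: np.ndarray,
    vertex: np.ndarray,
    b: np.ndarray,
    sagittal_normal: np.ndarray = MEDIOLATERAL_AXIS,
    projected: bool = True,
) -> np.ndarray:
    """Signed flexion at ``vertex`` formed by points ``a`` and ``b``, degrees.

    Both limb vectors are projected onto the plane orthogonal to
    ``sagittal_normal`` (set ``projected=False`` to use the raw 3-D
    included angle instead); the magnitude is 180° minus the included
    angle (collinear segments → 0°), and the sign is that of the
    cross-product component along ``sagittal_normal``.  Accepts single
    points or ``(..., 3)`` stacks.
    """
    a = np.asarray(a, dtype=float)
    vertex = np.asarray(vertex, dtype=float)
    b = np.asarray(b, dtype=float)
    n = np.asarray(sagittal_normal, dtype=float)
    n = n / np.linalg.norm(n)
    u = a - vertex
    v = b - vertex
    if projected:
        u = u - np.sum(u * n, axis=-1, keepdims=True) * n
        v = v - np.sum(v * n, axis=-1, keepdims=True) * n
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu < 1e-12) or np.any(nv < 1e-12):
        raise ValidationError("degenerate geometry: zero-length projected segment")
    cosang = np.clip(np.sum(u * v, axis=-1) / (nu * nv), -1.0, 1.0)
    included = np.degrees(np.arccos(cosang))
    sign = np.sign(np.sum(np.cross(u, v) * n, axis=-1))
    sign = np.where(sign == 0, 1.0, sign)
    return sign * (180.0 - included)


def _interpolate_gaps(traj: np.ndarray, present: np.ndarray, max_gap: int, name: str) -> np.ndarray:
    """Fill interior gaps of ``<= max_gap`` frames linearly; hold short edge gaps."""
    n = traj.shape[0]
    if present.all():
        return traj
    # identify runs of missing frames
    missing = ~present
    idx = np.arange(n)
    runs = []
    start = None
    for i in range(n):
        if missing[i] and start is None:
            start = i
        elif not missing[i] and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, n - 1))
    for lo, hi in runs:
        if hi - lo + 1 > max_gap:
            raise ValidationError(
                f"keypoint {name!r}: gap of {hi - lo + 1} frames exceeds the "
                f"{max_gap}-frame interpolation limit"
            )
    out = traj.copy()
    good = idx[present]
    for d in range(3):
        out[missing, d] = np.interp(idx[missing], good, traj[present, d])
    return out


def angles_from_skeleton(
    skel: FusedSkeletonSeries,
    side: str = "right",
    cfg: StatsConfig | None = None,
    max_gap_frames: int = 3,
    min_presence: float = 0.9,
    apply_filter: bool = True,
    hip_reference: str = "same_side",
    projected: bool = True,
) -> dict[str, AngleWaveform]:
    """Hip and knee flexion waveforms from a fused skeleton.

    The low-pass filter is applied to the keypoint trajectories, not to the
    angle waveforms.  Hip flexion uses the same-side shoulder by default
    (``hip_reference="shoulder_midpoint"`` uses the midpoint of both
    shoulders); the sagittal normal is oriented per joint and side so
    flexion is positive.  ``projected=False`` switches to the raw 3-D
    included angle.
    """
    cfg = cfg or StatsConfig()
    if side not in ("right", "left"):
        raise ValidationError(f"side must be 'right' or 'left', got {side!r}")
    if hip_reference not in ("same_side", "shoulder_midpoint"):
        raise ValidationError(f"unknown hip_reference {hip_reference!r}")
    required = [f"{side}_shoulder", f"{side}_hip", f"{side}_knee", f"{side}_ankle"]
    if hip_reference == "shoulder_midpoint":
        other = "left" if side == "right" else "right"
        required.append(f"{other}_shoulder")
    trajs = {}
    too_missing = []
    for name in required:
        k = KEYPOINT_INDEX[name]
        traj = skel.positions[:, k, :]
        present = np.isfinite(traj).all(axis=-1)
        if present.mean() < min_presence:
            too_missing.append(name)
            continue
        trajs[name] = _interpolate_gaps(traj, present, max_gap_frames, name)
    if too_missing:
        raise ValidationError(f"excessive missingness for keypoints: {too_missing}")
    if apply_filter:
        for name in required:
            trajs[name] = lowpass(
                trajs[name], skel.sample_rate, cfg.filter_cutoff, cfg.filter_order
            )
    # sagittal normal signs: +Y gives positive hip flexion (thigh forward) and
    # -Y positive knee flexion (ankle behind the thigh line) on the right side;
    # both flip for the left side.
    s = 1.0 if side == "right" else -1.0
    hip_normal = s * MEDIOLATERAL_AXIS
    knee_normal = -s * MEDIOLATERAL_AXIS
    if hip_reference == "shoulder_midpoint":
        other = "left" if side == "right" else "right"
        hip_ref_traj = 0.5 * (trajs[f"{side}_shoulder"] + trajs[f"{other}_shoulder"])
    else:
        hip_ref_traj = trajs[f"{side}_shoulder"]
    hip = flexion_angle(
        hip_ref_traj, trajs[f"{side}_hip"], trajs[f"{side}_knee"], hip_normal, projected
    )
    knee = flexion_angle(
        trajs[f"{side}_hip"], trajs[f"{side}_knee"], trajs[f"{side}_ankle"], knee_normal, projected
    )
    t = skel.timestamps
    return {
        "hip": AngleWaveform("hip", side, skel.sample_rate, hip, t),
        "knee": AngleWaveform("knee", side, skel.sample_rate, knee, t),
    }


def trial_angles(
    frame_sets: list[KeypointFrameSet],
    extrinsics: dict[str, CameraExtrinsics],
    side: str = "right",
    cfg: StatsConfig | None = None,
    gate_distance: float = 0.15,
    filter_per_camera: bool = False,
    **angle_kwargs,
) -> dict[str, AngleWaveform]:
    """Convenience: camera streams → world → fused skeleton → angle waveforms.

    By default the low-pass filter runs on the fused trajectories;
    ``filter_per_camera=True`` filters each camera's fully observed
    trajectories before fusion instead (only meaningful for dropout-free
    streams, since filtering cannot cross gaps).
    """
    cfg = cfg or StatsConfig()
    world = []
    for fs in frame_sets:
        if fs.frame_of_reference == "camera":
            fs = to_world(fs, extrinsics[fs.camera_id])
        if filter_per_camera:
            if not fs.present().all():
                raise ValidationError(
                    f"camera {fs.camera_id!r}: per-camera filtering requires "
                    "gap-free streams"
                )
            fs = KeypointFrameSet(
                fs.camera_id,
                fs.sample_rate,
                fs.timestamps,
                lowpass(fs.positions, fs.sample_rate, cfg.filter_cutoff, cfg.filter_order),
                fs.confidence,
                "world",
            )
        world.append(fs)
    skel = fuse_keypoints(world, gate_distance=gate_distance)
    return angles_from_skeleton(
        skel, side=side, cfg=cfg, apply_filter=not filter_per_camera, **angle_kwargs
    )
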