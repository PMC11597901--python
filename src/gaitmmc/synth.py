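"""Synthetic multi-camera gait trials with known ground truth.

The generator emulates a treadmill validation study: a walking skeleton whose
hip/knee flexion follows smooth periodic waveforms, observed by

* three depth cameras (front, back, right side) at 30 Hz, subject to
  joint-center mislocalization offsets, a depth-surface bias pulling every
  point toward the observing camera, isotropic Gaussian keypoint noise and
  random dropout;
* a marker-based reference stream at 100 Hz (truth + small angle noise);
* force plates at 1000 Hz whose vertical-force bursts start exactly at the
  ground-truth heel strikes.

Joint-angle waveforms are truncated Fourier series in gait phase
φ ∈ [0, 1): smooth, periodic, and exactly recoverable, standing in for real
gait curves.  Forward kinematics is built so that re-deriving hip/knee
flexion from the generated keypoints by the vector method returns the model
waveform exactly — the defining self-consistency contract of the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from gaitmmc.types import (
    COCO_KEYPOINTS,
    KEYPOINT_INDEX,
    AngleWaveform,
    CameraExtrinsics,
    GrfSeries,
    KeypointFrameSet,
    TrialRecord,
    ValidationError,
)

_JOINTS = ("hip", "knee")


# ---------------------------------------------------------------------------
# gait waveform model


@dataclass
class GaitModel:
    """Per-joint Fourier description of angle vs gait phase.

    ``coefficients[joint] = (a0, a, b)`` encodes
    ``angle(φ) = a0 + Σ_h a_h cos(2πhφ) + b_h sin(2πhφ)`` in degrees.
    """

    coefficients: dict[str, tuple[float, np.ndarray, np.ndarray]]
    cycle_duration: float
    stance_fraction: float

    def __post_init__(self) -> None:
        if self.cycle_duration <= 0:
            raise ValidationError("cycle_duration must be positive")
        if not 0 < self.stance_fraction < 1:
            raise ValidationError("stance_fraction must lie in (0, 1)")
        for joint, (a0, a, b) in self.coefficients.items():
            a = np.asarray(a, dtype=float)
            b = np.asarray(b, dtype=float)
            if a.size < 1 or a.size != b.size:
                raise ValidationError(f"{joint}: need H >= 1 matching cos/sin coefficients")
            self.coefficients[joint] = (float(a0), a, b)


def angle_at_phase(model: GaitModel, joint: str, phase) -> np.ndarray | float:
    """Evaluate the model waveform at any real phase (wrapped mod 1)."""
    if joint not in model.coefficients:
        raise ValidationError(f"unknown joint {joint!r}")
    a0, a, b = model.coefficients[joint]
    phi = np.asarray(phase, dtype=float) % 1.0
    h = np.arange(1, a.size + 1)
    ang = a0 + (a * np.cos(2 * np.pi * np.outer(phi, h))).sum(axis=-1) + (
        b * np.sin(2 * np.pi * np.outer(phi, h))
    ).sum(axis=-1)
    return ang.reshape(np.shape(phase)) if np.ndim(phase) else float(ang[0])


def _periodic_bump(phi: np.ndarray, center: float, width: float) -> np.ndarray:
    d = (phi - center + 0.5) % 1.0 - 0.5
    return np.exp(-0.5 * (d / width) ** 2)


def _fourier_fit(values: np.ndarray, n_harmonics: int) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares truncation of a periodic sample to ``n_harmonics`` terms."""
    spec = np.fft.rfft(values) / values.size
    a0 = float(spec[0].real)
    a = 2 * spec[1 : n_harmonics + 1].real
    b = -2 * spec[1 : n_harmonics + 1].imag
    return a0, a, b


def _shift_phase(
    coeffs: tuple[float, np.ndarray, np.ndarray], s: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Coefficients of ``f(φ + s)`` given those of ``f(φ)``."""
    a0, a, b = coeffs
    h = np.arange(1, a.size + 1)
    th = 2 * np.pi * h * s
    return a0, a * np.cos(th) + b * np.sin(th), -a * np.sin(th) + b * np.cos(th)


def default_gait_model(speed: float, n_harmonics: int = 4) -> GaitModel:
    """A deterministic walking model for a given treadmill speed.

    Waveform shapes are chosen to resemble normal sagittal gait: hip flexion
    peaking in late swing (≈ +30°) with extension ≈ −10° in late stance; knee
    flexion with a small stance bump (≈ 18°) and a large swing peak (≈ 60°).
    The knee waveform is phase-shifted so its global minimum (terminal-swing
    full extension) lands exactly at φ = 0, the heel strike — this is what
    makes knee-minimum segmentation commensurate with GRF segmentation.
    Cycle duration decreases monotonically with speed.
    """
    if speed <= 0:
        raise ValidationError("speed must be positive")
    phi = np.arange(512) / 512.0
    # bump widths are kept broad enough that the truncated waveform is
    # faithfully representable at the 30 Hz markerless rate (expected
    # per-cycle peak undersampling ≈ 0.1–0.2°)
    # the midstance valley is kept several degrees above the terminal-swing
    # minimum so that cycle segmentation by the global knee minimum stays
    # unambiguous under participant-level waveform perturbation and noise
    knee_proto = (
        2.0
        + 18.0 * _periodic_bump(phi, 0.17, 0.10)
        + 55.0 * _periodic_bump(phi, 0.72, 0.12)
        + 13.0 * _periodic_bump(phi, 0.43, 0.16)
    )
    hip_proto = 10.0 + 20.0 * np.cos(2 * np.pi * (phi - 0.9)) + 2.0 * np.cos(
        4 * np.pi * (phi - 0.15)
    )
    knee = _fourier_fit(knee_proto, n_harmonics)
    fine = np.arange(20000) / 20000.0
    h = np.arange(1, n_harmonics + 1)
    knee_curve = knee[0] + (knee[1] * np.cos(2 * np.pi * np.outer(fine, h))).sum(-1) + (
        knee[2] * np.sin(2 * np.pi * np.outer(fine, h))
    ).sum(-1)
    s = float(fine[np.argmin(knee_curve)])
    coeffs = {
        "knee": _shift_phase(knee, s),
        "hip": _shift_phase(_fourier_fit(hip_proto, n_harmonics), s),
    }
    cycle_duration = 0.90 + 0.25 / speed
    stance_fraction = float(np.clip(0.62 - 0.05 * (speed - 1.0), 0.5, 0.7))
    return GaitModel(coeffs, cycle_duration, stance_fraction)


def model_discrete_params(model: GaitModel, joint: str, n: int = 2000) -> dict[str, float]:
    """Ground-truth max/min/ROM of one joint's waveform over a cycle."""
    w = angle_at_phase(model, joint, np.arange(n) / n)
    return {"max": float(w.max()), "min": float(w.min()), "rom": float(w.max() - w.min())}


# ---------------------------------------------------------------------------
# skeleton forward kinematics


@dataclass
class Anthropometry:
    """Segment geometry as fractions of stature (standard anthropometric tables)."""

    stature: float = 1.75
    trunk_fraction: float = 0.288  # hip -> shoulder
    thigh_fraction: float = 0.245  # hip -> knee
    shank_fraction: float = 0.246  # knee -> ankle
    hip_height_fraction: float = 0.530
    pelvis_width: float = 0.18
    shoulder_width: float = 0.26

    def __post_init__(self) -> None:
        fracs = (self.trunk_fraction, self.thigh_fraction, self.shank_fraction)
        if self.stature <= 0 or any(f <= 0 for f in fracs) or self.pelvis_width <= 0:
            raise ValidationError("anthropometry lengths must be positive")
        if sum(fracs) >= 1:
            raise ValidationError("segment fractions must sum below 1")


def skeleton_pose(
    model: GaitModel,
    anthropometry: Anthropometry,
    phase,
    treadmill_speed: float = 1.0,
) -> np.ndarray:
    """World positions of the 17 COCO keypoints at the given phase(s).

    Sagittal-plane chain per side: a vertical trunk segment from hip to
    shoulder, thigh from hip to knee (rotated forward by the hip flexion
    angle), shank from knee to ankle (thigh direction rotated back by the
    knee flexion angle); the left side runs half a cycle out of phase.
    The pelvis oscillates slightly vertically and laterally; head and arm
    keypoints are placed by fixed offsets plus a small arm swing.

    Returns ``(17, 3)`` for a scalar phase, ``(n, 17, 3)`` for an array.
    """
    phi = np.atleast_1d(np.asarray(phase, dtype=float))
    n = phi.size
    a = anthropometry
    L_tr = a.trunk_fraction * a.stature
    L_th = a.thigh_fraction * a.stature
    L_sh = a.shank_fraction * a.stature

    pelvis = np.zeros((n, 3))
    pelvis[:, 0] = 0.015 * np.sin(2 * np.pi * phi)
    pelvis[:, 1] = 0.020 * np.sin(2 * np.pi * phi)
    pelvis[:, 2] = a.hip_height_fraction * a.stature + 0.012 * np.sin(4 * np.pi * phi)

    pos = np.zeros((n, 17, 3))

    def leg(side: str, side_phi: np.ndarray, y_sign: float) -> None:
        alpha = np.radians(angle_at_phase(model, "hip", side_phi))
        beta = np.radians(angle_at_phase(model, "knee", side_phi))
        hip = pelvis + np.array([0.0, y_sign * a.pelvis_width / 2, 0.0])
        thigh_dir = np.stack([np.sin(alpha), np.zeros(n), -np.cos(alpha)], axis=-1)
        shank_ang = alpha - beta
        shank_dir = np.stack([np.sin(shank_ang), np.zeros(n), -np.cos(shank_ang)], axis=-1)
        knee = hip + L_th * thigh_dir
        ankle = knee + L_sh * shank_dir
        shoulder = hip + np.array(
            [0.0, y_sign * (a.shoulder_width - a.pelvis_width) / 2, L_tr]
        )
        pos[:, KEYPOINT_INDEX[f"{side}_hip"]] = hip
        pos[:, KEYPOINT_INDEX[f"{side}_knee"]] = knee
        pos[:, KEYPOINT_INDEX[f"{side}_ankle"]] = ankle
        pos[:, KEYPOINT_INDEX[f"{side}_shoulder"]] = shoulder
        # arm swing opposes the ipsilateral leg
        L_ua, L_fa = 0.186 * a.stature, 0.146 * a.stature
        theta = 0.25 * np.sin(2 * np.pi * (side_phi + 0.5))
        elbow = shoulder + L_ua * np.stack(
            [np.sin(theta), np.zeros(n), -np.cos(theta)], axis=-1
        )
        wrist = elbow + L_fa * np.stack(
            [np.sin(theta - 0.25), np.zeros(n), -np.cos(theta - 0.25)], axis=-1
        )
        pos[:, KEYPOINT_INDEX[f"{side}_elbow"]] = elbow
        pos[:, KEYPOINT_INDEX[f"{side}_wrist"]] = wrist

    leg("right", phi, -1.0)
    leg("left", phi + 0.5, +1.0)

    neck = pelvis + np.array([0.0, 0.0, L_tr])
    head_offsets = {
        "nose": (0.09, 0.0, 0.16),
        "left_eye": (0.07, 0.03, 0.19),
        "right_eye": (0.07, -0.03, 0.19),
        "left_ear": (0.01, 0.07, 0.17),
        "right_ear": (0.01, -0.07, 0.17),
    }
    for name, off in head_offsets.items():
        pos[:, KEYPOINT_INDEX[name]] = neck + np.array(off)

    return pos[0] if np.ndim(phase) == 0 else pos


# ---------------------------------------------------------------------------
# observation models


@dataclass
class ObservationModel:
    """Error mechanisms of the markerless rig.

    ``joint_center_offsets`` maps keypoint names to constant world-frame
    offset vectors (metres) emulating systematic joint-center
    mislocalization by the pose estimator; ``depth_surface_bias`` shifts
    every observed point toward the observing camera along the camera→point
    ray, emulating depth sensors reporting the nearest body surface.
    """

    keypoint_noise_sd: float = 0.010
    joint_center_offsets: dict[str, np.ndarray] = field(default_factory=dict)
    depth_surface_bias: float = 0.0
    dropout_prob: float = 0.02
    confidence_mean: float = 0.85
    confidence_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.keypoint_noise_sd < 0:
            raise ValidationError("keypoint_noise_sd must be >= 0")
        if not 0 <= self.dropout_prob < 1:
            raise ValidationError("dropout_prob must lie in [0, 1)")
        self.joint_center_offsets = {
            k: np.asarray(v, dtype=float) for k, v in self.joint_center_offsets.items()
        }


def default_extrinsics(distance: float = 3.0, height: float = 1.2) -> list[CameraExtrinsics]:
    """Three cameras: front (+X), back (−X) and right side (−Y), facing the subject."""
    placements = {
        "front": np.array([distance, 0.0, height]),
        "back": np.array([-distance, 0.0, height]),
        "side": np.array([0.0, -distance, height]),
    }
    target = np.array([0.0, 0.0, 1.0])
    out = []
    for cam_id, pos in placements.items():
        f = target - pos
        f = f / np.linalg.norm(f)
        up = np.array([0.0, 0.0, 1.0])
        r = np.cross(f, up)
        r = r / np.linalg.norm(r)
        u = np.cross(f, r)
        rotation = np.column_stack([r, u, f])
        out.append(CameraExtrinsics(camera_id=cam_id, rotation=rotation, translation=pos))
    return out


def _interp_positions(
    t_src: np.ndarray, pos_src: np.ndarray, t_dst: np.ndarray
) -> np.ndarray:
    flat = pos_src.reshape(len(t_src), -1)
    out = np.empty((len(t_dst), flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(t_dst, t_src, flat[:, j])
    return out.reshape(len(t_dst), *pos_src.shape[1:])


def observe_markerless(
    true_poses: KeypointFrameSet,
    extrinsics_list: list[CameraExtrinsics],
    obs_model: ObservationModel,
    rate: float = 30.0,
    output_frame: str = "camera",
) -> list[KeypointFrameSet]:
    """Simulate the per-camera keypoint streams from a true pose stream.

    Per camera: sample truth at ``rate``, add per-joint center offsets, pull
    each point toward the camera by ``depth_surface_bias`` along the
    camera→point ray, add isotropic Gaussian noise, and drop keypoints with
    ``dropout_prob`` (absent positions, confidence 0).  Deterministic for a
    fixed :class:`ObservationModel` seed.
    """
    if not extrinsics_list:
        raise ValidationError("need at least one camera")
    if rate > true_poses.sample_rate + 1e-9:
        raise ValidationError(
            f"requested {rate} Hz exceeds the true-pose rate {true_poses.sample_rate} Hz"
        )
    t0, t1 = true_poses.timestamps[0], true_poses.timestamps[-1]
    n = int(np.floor((t1 - t0) * rate + 1e-9)) + 1
    t = t0 + np.arange(n) / rate
    base = _interp_positions(true_poses.timestamps, true_poses.positions, t)

    offsets = np.zeros((17, 3))
    for name, off in obs_model.joint_center_offsets.items():
        offsets[KEYPOINT_INDEX[name]] = off

    rng = np.random.default_rng(obs_model.seed)
    out = []
    for ext in extrinsics_list:
        p = base + offsets[None]
        if obs_model.depth_surface_bias != 0.0:
            ray = ext.position[None, None, :] - p
            norm = np.linalg.norm(ray, axis=-1, keepdims=True)
            p = p + obs_model.depth_surface_bias * ray / norm
        if obs_model.keypoint_noise_sd > 0:
            p = p + rng.normal(0.0, obs_model.keypoint_noise_sd, size=p.shape)
        conf = np.clip(
            rng.normal(obs_model.confidence_mean, obs_model.confidence_sd, size=(n, 17)),
            0.05,
            1.0,
        )
        if obs_model.dropout_prob > 0:
            drop = rng.random((n, 17)) < obs_model.dropout_prob
            p = np.where(drop[..., None], np.nan, p)
            conf = np.where(drop, 0.0, conf)
        if output_frame == "camera":
            p = (p - ext.translation) @ ext.rotation  # R^T (p - t), batched
        elif output_frame != "world":
            raise ValidationError(f"unknown output_frame {output_frame!r}")
        out.append(
            KeypointFrameSet(
                camera_id=ext.camera_id,
                sample_rate=rate,
                timestamps=t,
                positions=p,
                confidence=conf,
                frame_of_reference=output_frame,
            )
        )
    return out


def observe_reference(
    true_angles: dict[str, AngleWaveform],
    marker_noise_sd_deg: float = 0.3,
    rate: float = 100.0,
    seed: int = 0,
    constant_offset_deg: float = 0.0,
) -> dict[str, AngleWaveform]:
    """Reference-system angle streams: truth resampled plus i.i.d. noise."""
    if marker_noise_sd_deg < 0:
        raise ValidationError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = {}
    for joint, wf in true_angles.items():
        t0, t1 = wf.timestamps[0], wf.timestamps[-1]
        n = int(np.floor((t1 - t0) * rate + 1e-9)) + 1
        t = t0 + np.arange(n) / rate
        v = np.interp(t, wf.timestamps, wf.values) + constant_offset_deg
        if marker_noise_sd_deg > 0:
            v = v + rng.normal(0.0, marker_noise_sd_deg, size=n)
        out[joint] = AngleWaveform(joint, wf.side, rate, v, t)
    return out


def synth_grf(
    model: GaitModel,
    duration: float,
    rate: float = 1000.0,
    body_weight_n: float = 700.0,
    phase0: float = 0.0,
) -> GrfSeries:
    """Vertical GRF: zero in swing, a double-bump burst during stance.

    The burst includes a sharp heel-strike transient so the rising
    0→positive crossing is steep; it starts exactly at each ground-truth
    heel strike (gait phase 0).
    """
    if duration < model.cycle_duration:
        raise ValidationError("duration must cover at least one cycle")
    n = int(np.floor(duration * rate + 1e-9)) + 1
    t = np.arange(n) / rate
    phi = (t / model.cycle_duration + phase0) % 1.0
    sf = model.stance_fraction
    u = phi / sf
    stance = phi < sf
    base = 1.15 * np.sin(np.pi * u) + 0.3 * np.sin(3 * np.pi * u)
    transient = 0.15 * (1.0 - np.exp(-u / 0.003)) * np.exp(-u / 0.08)
    force = np.where(stance, body_weight_n * (base + transient), 0.0)
    force = np.maximum(force, 0.0)
    return GrfSeries(sample_rate=rate, vertical_force=force, timestamps=t)


def true_cycle_starts(model: GaitModel, duration: float, phase0: float = 0.0) -> np.ndarray:
    """Times within [0, duration] at which gait phase crosses 0."""
    T = model.cycle_duration
    k0 = int(np.ceil(phase0 - 1e-12))
    starts = []
    k = k0
    while (k - phase0) * T <= duration + 1e-12:
        s = (k - phase0) * T
        if s >= 0:
            starts.append(s)
        k += 1
    return np.asarray(starts)


# ---------------------------------------------------------------------------
# full study generation


@dataclass
class SyntheticTrial:
    """One generated trial: observed streams plus the generating truth."""

    trial: TrialRecord
    truth_angles: dict[str, AngleWaveform]
    truth_cycle_starts: np.ndarray
    truth_params: dict[str, dict[str, float]]
    model: GaitModel
    anthropometry: Anthropometry
    phase0: float
    extrinsics: list[CameraExtrinsics] = field(default_factory=default_extrinsics)


def _perturb_model(model: GaitModel, rng: np.random.Generator,
                   amp_scale_sd: float, offset_sd: float, coeff_sd: float,
                   duration_sd: float) -> GaitModel:
    coeffs = {}
    for joint, (a0, a, b) in model.coefficients.items():
        scale = rng.normal(1.0, amp_scale_sd)
        coeffs[joint] = (
            a0 * scale + rng.normal(0.0, offset_sd),
            a * scale + rng.normal(0.0, coeff_sd, size=a.size),
            b * scale + rng.normal(0.0, coeff_sd, size=b.size),
        )
    return GaitModel(
        coefficients=coeffs,
        cycle_duration=model.cycle_duration * max(rng.normal(1.0, duration_sd), 0.5),
        stance_fraction=model.stance_fraction,
    )


def generate_trial(
    model: GaitModel,
    anthropometry: Anthropometry,
    obs_model: ObservationModel,
    participant_id: str = "P01",
    session: int = 1,
    speed: float = 1.0,
    duration: float = 60.0,
    reference_rate: float = 100.0,
    markerless_rate: float = 30.0,
    grf_rate: float = 1000.0,
    phase0: float = 0.0,
    reference_noise_sd_deg: float = 0.3,
    extrinsics: list[CameraExtrinsics] | None = None,
    body_weight_n: float = 700.0,
) -> SyntheticTrial:
    """Generate one complete trial from a fixed model and observation model."""
    extrinsics = extrinsics if extrinsics is not None else default_extrinsics()
    n_ref = int(np.floor(duration * reference_rate + 1e-9)) + 1
    t_ref = np.arange(n_ref) / reference_rate
    phi = (t_ref / model.cycle_duration + phase0) % 1.0

    truth_angles = {
        joint: AngleWaveform(
            joint, "right", reference_rate, angle_at_phase(model, joint, phi), t_ref
        )
        for joint in _JOINTS
    }
    poses = skeleton_pose(model, anthropometry, phi, treadmill_speed=speed)
    true_poses = KeypointFrameSet(
        camera_id="truth",
        sample_rate=reference_rate,
        timestamps=t_ref,
        positions=poses,
        confidence=np.ones((n_ref, 17)),
        frame_of_reference="world",
    )
    markerless = observe_markerless(true_poses, extrinsics, obs_model, rate=markerless_rate)
    reference = observe_reference(
        truth_angles,
        marker_noise_sd_deg=reference_noise_sd_deg,
        rate=reference_rate,
        seed=obs_model.seed + 7919,
    )
    grf = synth_grf(model, duration, rate=grf_rate, body_weight_n=body_weight_n, phase0=phase0)
    record = TrialRecord(
        participant_id=participant_id,
        session=session,
        speed=speed,
        markerless={fs.camera_id: fs for fs in markerless},
        reference=reference,
        grf=grf,
    )
    return SyntheticTrial(
        trial=record,
        truth_angles=truth_angles,
        truth_cycle_starts=true_cycle_starts(model, duration, phase0),
        truth_params={j: model_discrete_params(model, j) for j in _JOINTS},
        model=model,
        anthropometry=anthropometry,
        phase0=phase0,
        extrinsics=extrinsics,
    )


def generate_study(
    n_participants: int = 15,
    sessions: int = 2,
    speeds: tuple[float, ...] = (0.7, 1.0, 1.3),
    obs_model: ObservationModel | None = None,
    seed: int = 0,
    duration: float = 60.0,
    participant_amp_scale_sd: float = 0.06,
    participant_offset_sd: float = 2.0,
    participant_coeff_sd: float = 0.8,
    participant_duration_sd: float = 0.05,
    session_coeff_sd: float = 0.20,
    session_offset_sd: float = 0.40,
    session_keypoint_offset_sd: float = 0.003,
    stature_mean: float = 1.75,
    stature_sd: float = 0.10,
    **trial_kwargs,
) -> list[SyntheticTrial]:
    """Generate the full test–retest study design.

    Defaults mirror a 15-participant, 2-session, 3-speed treadmill protocol.
    Each participant gets their own anthropometry and gait-model
    perturbation; session 2 re-uses the participant's parameters plus a
    small session-level waveform perturbation (≤ ~1° RMS) and fresh small
    per-keypoint localization offsets, producing test–retest structure.
    Fully deterministic per seed.
    """
    if n_participants < 2:
        raise ValidationError("need at least two participants for downstream statistics")
    if sessions < 1:
        raise ValidationError("sessions must be >= 1")
    obs_model = obs_model if obs_model is not None else ObservationModel()
    rng = np.random.default_rng(seed)
    extrinsics = default_extrinsics()
    trials: list[SyntheticTrial] = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        stature = float(np.clip(rng.normal(stature_mean, stature_sd), 1.45, 2.05))
        anthro = Anthropometry(stature=stature)
        base_models = {
            speed: _perturb_model(
                default_gait_model(speed),
                rng,
                participant_amp_scale_sd,
                participant_offset_sd,
                participant_coeff_sd,
                participant_duration_sd,
            )
            for speed in speeds
        }
        for session in range(1, sessions + 1):
            session_offsets = {
                name: rng.normal(0.0, session_keypoint_offset_sd, size=3)
                for name in COCO_KEYPOINTS
            }
            merged_offsets = dict(session_offsets)
            for name, off in obs_model.joint_center_offsets.items():
                merged_offsets[name] = merged_offsets.get(name, 0.0) + np.asarray(off, float)
            for speed in speeds:
                model = base_models[speed]
                if session > 1:
                    model = _perturb_model(
                        model, rng, 0.0, session_offset_sd, session_coeff_sd, 0.01
                    )
                trial_seed = int(rng.integers(0, 2**31 - 1))
                t_obs = replace(
                    obs_model, joint_center_offsets=merged_offsets, seed=trial_seed
                )
                trials.append(
                    generate_trial(
                        model,
                        anthro,
                        t_obs,
                        participant_id=pid,
                        session=session,
                        speed=speed,
                        duration=duration,
                        phase0=float(rng.random()),
                        extrinsics=extrinsics,
                        **trial_kwargs,
                    )
                )
    return trials
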