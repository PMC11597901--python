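"""Plain-text readers and writers for the formats the pipeline touches.

Exchange formats are deliberately text-only: a long-form keypoint CSV
(``camera,frame,time_s,keypoint,x_m,y_m,z_m,confidence``), a two-column GRF
CSV (``time_s,fz_N``), tab-delimited TRC for marker trajectories (standard
header, millimetres on disk, metres in memory) and a JSON/YAML extrinsics
file.  Binary mocap containers (C3D) are out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from gaitmmc.types import (
    COCO_KEYPOINTS,
    KEYPOINT_INDEX,
    CameraExtrinsics,
    GrfSeries,
    KeypointFrameSet,
    ValidationError,
)

KEYPOINT_CSV_COLUMNS = ["camera", "frame", "time_s", "keypoint", "x_m", "y_m", "z_m", "confidence"]


# ---------------------------------------------------------------------------
# keypoint tables


def read_keypoint_table(path: str | Path, frame_of_reference: str = "camera") -> list[KeypointFrameSet]:
    """Read a long-form keypoint CSV into one :class:`KeypointFrameSet` per camera.

    Rows are grouped by camera and sorted by time; unknown keypoint names and
    out-of-range confidences are rejected.  Missing detections may simply be
    omitted from the file (or carry NaN coordinates).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: malformed CSV: {exc}") from exc
    missing_cols = set(KEYPOINT_CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {sorted(missing_cols)}")
    bad = ~df["keypoint"].isin(COCO_KEYPOINTS)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header + 1-based
        raise ValidationError(
            f"{path}:{line}: unknown keypoint name {df.loc[df.index[bad][0], 'keypoint']!r}"
        )
    if ((df["confidence"] < 0) | (df["confidence"] > 1)).any():
        raise ValidationError(f"{path}: confidence outside [0, 1]")

    out: list[KeypointFrameSet] = []
    for cam_id, grp in df.groupby("camera", sort=True):
        frames = np.sort(grp["frame"].unique())
        t_by_frame = grp.drop_duplicates("frame").set_index("frame")["time_s"].sort_index()
        t = t_by_frame.to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"{path}: non-monotone time within camera {cam_id!r}")
        if t.size >= 2:
            rate = 1.0 / float(np.median(np.diff(t)))
        else:
            rate = 1.0
        n = frames.size
        pos = np.full((n, 17, 3), np.nan)
        conf = np.zeros((n, 17))
        frame_row = {f: i for i, f in enumerate(frames)}
        ki = grp["keypoint"].map(KEYPOINT_INDEX).to_numpy()
        fi = grp["frame"].map(frame_row).to_numpy()
        pos[fi, ki, 0] = grp["x_m"].to_numpy(dtype=float)
        pos[fi, ki, 1] = grp["y_m"].to_numpy(dtype=float)
        pos[fi, ki, 2] = grp["z_m"].to_numpy(dtype=float)
        conf[fi, ki] = grp["confidence"].to_numpy(dtype=float)
        # rows with NaN coordinates are absent detections
        absent = ~np.isfinite(pos).all(axis=-1)
        pos[absent] = np.nan
        conf[absent] = 0.0
        out.append(
            KeypointFrameSet(
                camera_id=str(cam_id),
                sample_rate=rate,
                timestamps=t,
                positions=pos,
                confidence=conf,
                frame_of_reference=frame_of_reference,
            )
        )
    if not out:
        raise ValidationError(f"{path}: no keypoint rows")
    return out


def write_keypoint_table(path: str | Path, frame_sets: list[KeypointFrameSet]) -> None:
    """Write frame sets to the long-form CSV (absent detections omitted)."""
    records = []
    for fs in frame_sets:
        present = fs.present()
        for i in range(fs.n_frames):
            for k in np.flatnonzero(present[i]):
                x, y, z = fs.positions[i, k]
                records.append(
                    (fs.camera_id, i, fs.timestamps[i], COCO_KEYPOINTS[k], x, y, z, fs.confidence[i, k])
                )
    df = pd.DataFrame.from_records(records, columns=KEYPOINT_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# TRC marker trajectories


def read_trc(path: str | Path) -> tuple[dict[str, np.ndarray], float, np.ndarray]:
    """Read a standard TRC file.

    Returns ``(trajectories, data_rate, timestamps)`` with trajectories in
    metres (TRC stores millimetres), keyed by marker name.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise ValidationError(f"{path}: truncated TRC file")
    # line 3 (index 2): DataRate CameraRate NumFrames NumMarkers Units ...
    meta_keys = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    try:
        rate = float(meta["DataRate"])
        n_frames = int(meta["NumFrames"])
        n_markers = int(meta["NumMarkers"])
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"{path}: bad TRC header: {exc}") from exc
    units = meta.get("Units", "mm")
    scale = {"mm": 1e-3, "m": 1.0, "cm": 1e-2}.get(units)
    if scale is None:
        raise ValidationError(f"{path}: unsupported TRC units {units!r}")
    header_cells = lines[3].split("\t")
    marker_names = [c for c in header_cells[2:] if c.strip()]
    if len(marker_names) != n_markers:
        raise ValidationError(
            f"{path}: header declares {n_markers} markers but names row has {len(marker_names)}"
        )
    data_rows = [ln for ln in lines[5:] if ln.strip()]
    if len(data_rows) != n_frames:
        raise ValidationError(
            f"{path}: header declares {n_frames} frames but file has {len(data_rows)}"
        )
    data = np.array([[float(c) for c in row.split("\t")[1:]] for row in data_rows])
    if data.shape[1] != 1 + 3 * n_markers:
        raise ValidationError(f"{path}: data width inconsistent with {n_markers} markers")
    timestamps = data[:, 0]
    trajectories = {
        name: data[:, 1 + 3 * i : 4 + 3 * i] * scale for i, name in enumerate(marker_names)
    }
    return trajectories, rate, timestamps


def write_trc(
    path: str | Path,
    trajectories: Mapping[str, np.ndarray],
    rate: float,
    timestamps: np.ndarray,
) -> None:
    """Write marker trajectories (metres in memory) as a standard mm TRC file."""
    names = list(trajectories)
    n_frames = len(timestamps)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{rate:g}\t{rate:g}\t{n_frames}\t{len(names)}\tmm\t{rate:g}\t1\t{n_frames}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\t\n")
        axes = "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(names)))
        fh.write("\t\t" + axes + "\n")
        for i, t in enumerate(timestamps):
            cells = [str(i + 1), f"{t:.6f}"]
            for name in names:
                cells.extend(f"{v * 1e3:.6f}" for v in trajectories[name][i])
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# GRF tables


def read_grf_table(path: str | Path, spacing_rtol: float = 1e-3) -> GrfSeries:
    """Read a two-column ``time_s,fz_N`` CSV into a :class:`GrfSeries`."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{path}: empty GRF file")
    if not {"time_s", "fz_N"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns time_s,fz_N")
    t = df["time_s"].to_numpy(dtype=float)
    f = df["fz_N"].to_numpy(dtype=float)
    if np.any(f < 0):
        raise ValidationError(f"{path}: negative force")
    if t.size < 2:
        raise ValidationError(f"{path}: need at least two samples")
    dt = np.diff(t)
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > spacing_rtol * med):
        raise ValidationError(f"{path}: irregular sampling beyond tolerance")
    return GrfSeries(sample_rate=1.0 / med, vertical_force=f, timestamps=t)


def write_grf_table(path: str | Path, grf: GrfSeries) -> None:
    pd.DataFrame({"time_s": grf.timestamps, "fz_N": grf.vertical_force}).to_csv(
        path, index=False, float_format="%.9g"
    )


# ---------------------------------------------------------------------------
# run configuration


def load_config(path: str | Path) -> dict:
    """Load a study configuration mapping from a YAML (or JSON) file.

    Keys mirror the study runner's defaults: design sizes (``n_participants``,
    ``sessions``, ``speeds``, ``duration``, ``seed``), an ``observation``
    sub-mapping with observation-model fields, and a ``stats`` sub-mapping
    with statistics/filter settings.
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return data


# ---------------------------------------------------------------------------
# extrinsics


def read_extrinsics(path: str | Path) -> list[CameraExtrinsics]:
    """Read per-camera extrinsics from JSON or YAML.

    Expected structure: a list of ``{camera, rotation: 9 numbers row-major,
    translation: 3 numbers}`` mappings.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    out = []
    for entry in data:
        out.append(
            CameraExtrinsics(
                camera_id=str(entry["camera"]),
                rotation=np.asarray(entry["rotation"], dtype=float).reshape(3, 3),
                translation=np.asarray(entry["translation"], dtype=float),
            )
        )
    return out


def write_extrinsics(path: str | Path, extrinsics: list[CameraExtrinsics]) -> None:
    data = [
        {
            "camera": e.camera_id,
            "rotation": [float(v) for v in e.rotation.ravel()],
            "translation": [float(v) for v in e.translation],
        }
        for e in extrinsics
    ]
    path = Path(path)
    with path.open("w") as fh:
        if path.suffix == ".json":
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh)
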