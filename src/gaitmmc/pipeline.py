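"""End-to-end study orchestration and report rendering.

``run_validation_study`` drives the full chain on a synthetic study —
simulate → fuse/angles → cycles → reliability and accuracy tables — from a
single config mapping, writing CSV tables, formatted text tables,
mean ± SD waveform figures and a machine-readable JSON of every statistic.
All randomness flows from the single study seed.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from gaitmmc import agreement, cycles, kinematics
from gaitmmc.agreement import TrialSummary
from gaitmmc.synth import ObservationModel, SyntheticTrial, generate_study
from gaitmmc.types import AngleWaveform, StatsConfig, ValidationError

_JOINTS = ("hip", "knee")


def _trim(wave: AngleWaveform, edge_s: float) -> AngleWaveform:
    """Drop filter edge transients from both ends of a waveform."""
    if edge_s <= 0:
        return wave
    m = int(round(edge_s * wave.sample_rate))
    if wave.values.size <= 2 * m + 2:
        raise ValidationError("waveform too short after edge trimming")
    return AngleWaveform(
        wave.joint,
        wave.side,
        wave.sample_rate,
        wave.values[m:-m],
        wave.timestamps[m:-m],
    )


def summarize_markerless(
    trial: SyntheticTrial,
    cfg: StatsConfig | None = None,
    edge_trim_s: float = 0.5,
) -> list[TrialSummary]:
    """Markerless chain for one trial: fuse, angles, knee-min cycles, params."""
    cfg = cfg or StatsConfig()
    angles = kinematics.trial_angles(
        list(trial.trial.markerless.values()),
        {e.camera_id: e for e in trial.extrinsics},
        side="right",
        cfg=cfg,
    )
    angles = {j: _trim(w, edge_trim_s) for j, w in angles.items()}
    events = cycles.detect_knee_min_events(angles["knee"])
    out = []
    for joint in _JOINTS:
        ncs = cycles.segment_and_normalize(angles[joint], events, cfg.normalized_points)
        params = cycles.discrete_params(ncs, joint)
        out.append(
            TrialSummary(
                participant_id=trial.trial.participant_id,
                session=trial.trial.session,
                speed=trial.trial.speed,
                joint=joint,
                max=params.max,
                min=params.min,
                rom=params.rom,
                mean_cycle=ncs.mean,
            )
        )
    return out


def summarize_reference(
    trial: SyntheticTrial,
    cfg: StatsConfig | None = None,
) -> list[TrialSummary]:
    """Reference chain: GRF heel strikes segment the reference angle streams."""
    cfg = cfg or StatsConfig()
    events = cycles.detect_heel_strikes(trial.trial.grf)
    out = []
    for joint in _JOINTS:
        wave = trial.trial.reference[joint]
        ev = events
        # keep only events inside the angle stream's support
        mask = (ev.times >= wave.timestamps[0]) & (ev.times <= wave.timestamps[-1])
        ev = cycles.EventList(times=ev.times[mask], source=ev.source)
        ncs = cycles.segment_and_normalize(wave, ev, cfg.normalized_points)
        params = cycles.discrete_params(ncs, joint)
        out.append(
            TrialSummary(
                participant_id=trial.trial.participant_id,
                session=trial.trial.session,
                speed=trial.trial.speed,
                joint=joint,
                max=params.max,
                min=params.min,
                rom=params.rom,
                mean_cycle=ncs.mean,
            )
        )
    return out


def summarize_study(
    trials: list[SyntheticTrial],
    cfg: StatsConfig | None = None,
) -> tuple[list[TrialSummary], list[TrialSummary]]:
    """Process every trial through both chains; returns (mmc, reference)."""
    mmc: list[TrialSummary] = []
    ref: list[TrialSummary] = []
    for trial in trials:
        tid = (trial.trial.participant_id, trial.trial.session, trial.trial.speed)
        try:
            mmc.extend(summarize_markerless(trial, cfg))
            ref.extend(summarize_reference(trial, cfg))
        except ValidationError as exc:
            raise ValidationError(f"trial {tid}: {exc}") from exc
    return mmc, ref


# ---------------------------------------------------------------------------
# table rendering


def _fmt(x: float) -> str:
    return "—" if x is None or not np.isfinite(x) else f"{x:.2f}"


def render_table(df: pd.DataFrame, style: str) -> str:
    """Publication-style text table, ``value (lo hi)`` cells, 2-decimal rounding."""
    lines = []
    if style == "reliability":
        header = (
            f"{'Joint':<6}{'Speed':>6} | "
            f"{'Max ICC (95% CI)':<22}{'SEM':>6}{'MDC':>6} | "
            f"{'Min ICC (95% CI)':<22}{'SEM':>6}{'MDC':>6} | "
            f"{'ROM ICC (95% CI)':<22}{'SEM':>6}{'MDC':>6} | "
            f"{'RMSE (SD)':<14}{'LCC (95% CI)':<20}"
        )
        lines.append(header)
        lines.append("-" * len(header))
        for _, r in df.iterrows():
            cells = [f"{r['joint']:<6}{r['speed']:>6.1f} | "]
            for p in ("max", "min", "rom"):
                icc = f"{_fmt(r[f'icc_{p}'])} ({_fmt(r[f'icc_{p}_ci_low'])} {_fmt(r[f'icc_{p}_ci_high'])})"
                cells.append(f"{icc:<22}{_fmt(r[f'sem_{p}']):>6}{_fmt(r[f'mdc_{p}']):>6} | ")
            rmse = f"{_fmt(r['rmse_mean'])} ({_fmt(r['rmse_sd'])})"
            lcc = f"{_fmt(r['lcc'])} ({_fmt(r['lcc_ci_low'])} {_fmt(r['lcc_ci_high'])})"
            cells.append(f"{rmse:<14}{lcc:<20}")
            lines.append("".join(cells))
    elif style == "accuracy":
        header = (
            f"{'Joint':<6}{'Speed':>6} | "
            f"{'Max bias (LoA)':<24}{'r':>6} | "
            f"{'Min bias (LoA)':<24}{'r':>6} | "
            f"{'ROM bias (LoA)':<24}{'r':>6} | "
            f"{'RMSE (SD)':<14}{'LCC (95% CI)':<20}"
        )
        lines.append(header)
        lines.append("-" * len(header))
        for _, r in df.iterrows():
            cells = [f"{r['joint']:<6}{r['speed']:>6.1f} | "]
            for p in ("max", "min", "rom"):
                ba = f"{_fmt(r[f'bias_{p}'])} ({_fmt(r[f'loa_low_{p}'])} {_fmt(r[f'loa_high_{p}'])})"
                cells.append(f"{ba:<24}{_fmt(r[f'r_{p}']):>6} | ")
            rmse = f"{_fmt(r['rmse_mean'])} ({_fmt(r['rmse_sd'])})"
            lcc = f"{_fmt(r['lcc'])} ({_fmt(r['lcc_ci_low'])} {_fmt(r['lcc_ci_high'])})"
            cells.append(f"{rmse:<14}{lcc:<20}")
            lines.append("".join(cells))
    else:
        raise ValidationError(f"unknown table style {style!r}")
    return "\n".join(lines) + "\n"


def plot_waveforms(
    mmc: list[TrialSummary],
    ref: list[TrialSummary],
    speed: float,
    out_path: str | Path,
) -> None:
    """Mean ± SD waveform ribbons for both systems at one speed."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for ax, joint in zip(axes, _JOINTS):
        for summaries, label, color in ((mmc, "markerless", "tab:blue"), (ref, "reference", "tab:red")):
            stack = np.array(
                [s.mean_cycle for s in summaries if s.joint == joint and s.speed == speed]
            )
            if stack.size == 0:
                continue
            phase = np.linspace(0, 100, stack.shape[1])
            mean = stack.mean(axis=0)
            sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros_like(mean)
            ax.plot(phase, mean, color=color, label=label)
            ax.fill_between(phase, mean - sd, mean + sd, color=color, alpha=0.2)
        ax.set_title(f"{joint} flexion/extension, {speed} m/s")
        ax.set_xlabel("gait cycle [%]")
        ax.set_ylabel("angle [deg]")
        ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# study runner


DEFAULT_CONFIG: dict[str, Any] = {
    "n_participants": 15,
    "sessions": 2,
    "speeds": (0.7, 1.0, 1.3),
    "duration": 60.0,
    "seed": 0,
    "observation": {},  # ObservationModel field overrides
    "stats": {},  # StatsConfig field overrides
    "accuracy_sessions": (1, 2),
    "make_plots": True,
}


def run_validation_study(
    config: Mapping[str, Any] | str | Path | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Run the full synthetic validation study and assemble every report.

    Returns a dict with the three tables (``reliability``,
    ``accuracy_uncorrected``, ``accuracy_corrected`` DataFrames) plus the
    trial summaries; when ``out_dir`` is given, writes CSVs, formatted text
    tables, waveform figures per speed, and ``statistics.json``.
    """
    if isinstance(config, (str, Path)):
        from gaitmmc.io import load_config

        config = load_config(config)
    cfg_map = dict(DEFAULT_CONFIG)
    cfg_map.update(config or {})
    stats_cfg = StatsConfig(**cfg_map["stats"])
    obs_model = ObservationModel(**cfg_map["observation"])

    trials = generate_study(
        n_participants=cfg_map["n_participants"],
        sessions=cfg_map["sessions"],
        speeds=tuple(cfg_map["speeds"]),
        obs_model=obs_model,
        seed=cfg_map["seed"],
        duration=cfg_map["duration"],
    )
    mmc, ref = summarize_study(trials, stats_cfg)

    reliability = agreement.reliability_report(mmc, stats_cfg)
    acc_sessions = set(cfg_map["accuracy_sessions"])
    mmc_acc = [s for s in mmc if s.session in acc_sessions]
    ref_acc = [s for s in ref if s.session in acc_sessions]
    acc_raw = agreement.accuracy_report(mmc_acc, ref_acc, corrected=False, cfg=stats_cfg)
    acc_cor = agreement.accuracy_report(mmc_acc, ref_acc, corrected=True, cfg=stats_cfg)

    results = {
        "reliability": reliability,
        "accuracy_uncorrected": acc_raw,
        "accuracy_corrected": acc_cor,
        "summaries_mmc": mmc,
        "summaries_ref": ref,
        "trials": trials,
        "seed": cfg_map["seed"],
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        reliability.to_csv(out_dir / "reliability.csv", index=False)
        acc_raw.to_csv(out_dir / "accuracy_uncorrected.csv", index=False)
        acc_cor.to_csv(out_dir / "accuracy_corrected.csv", index=False)
        (out_dir / "reliability.txt").write_text(render_table(reliability, "reliability"))
        (out_dir / "accuracy_uncorrected.txt").write_text(render_table(acc_raw, "accuracy"))
        (out_dir / "accuracy_corrected.txt").write_text(render_table(acc_cor, "accuracy"))
        payload = {
            "seed": cfg_map["seed"],
            "n_participants": cfg_map["n_participants"],
            "speeds": list(cfg_map["speeds"]),
            "duration_s": cfg_map["duration"],
            "reliability": reliability.to_dict(orient="records"),
            "accuracy_uncorrected": acc_raw.to_dict(orient="records"),
            "accuracy_corrected": acc_cor.to_dict(orient="records"),
        }
        (out_dir / "statistics.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        if cfg_map["make_plots"]:
            for speed in cfg_map["speeds"]:
                plot_waveforms(mmc_acc, ref_acc, speed, out_dir / f"waveforms_{speed}.png")
    return results
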