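#!/usr/bin/env python
"""Inject a constant +6° hip offset and show the offset correction removes it.

A posterior→anterior shoulder joint-center shift of trunk_length·tan(6°)
biases the vector-computed hip flexion by exactly +6° at every instant
(the trunk stays vertical in the generator), emulating systematic
joint-center mislocalization by a pose estimator.  The uncorrected
waveform RMSE against the reference then sits at ≈6°; subtracting the mean
waveform difference per participant-session collapses it to the noise
floor, while every ROM statistic is untouched (a constant shift cannot
change a range).
"""

import json
from pathlib import Path

import numpy as np

from gaitmmc import agreement as ag
from gaitmmc.pipeline import summarize_study
from gaitmmc.synth import ObservationModel, generate_study

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    trunk_len = 0.288 * 1.75
    dx = trunk_len * np.tan(np.radians(6.0))
    obs = ObservationModel(
        keypoint_noise_sd=0.0,
        dropout_prob=0.0,
        joint_center_offsets={
            "right_shoulder": (dx, 0.0, 0.0),
            "left_shoulder": (dx, 0.0, 0.0),
        },
    )
    trials = generate_study(
        n_participants=8,
        sessions=1,
        speeds=(1.0,),
        obs_model=obs,
        seed=11,
        duration=30.0,
        stature_sd=0.0,
        participant_coeff_sd=0.0,
        session_keypoint_offset_sd=0.0,
    )
    mmc, ref = summarize_study(trials)
    raw = ag.accuracy_report(mmc, ref, corrected=False)
    cor = ag.accuracy_report(mmc, ref, corrected=True)

    report = {}
    for joint in ("hip", "knee"):
        r = float(raw.loc[raw.joint == joint, "rmse_mean"].iloc[0])
        c = float(cor.loc[cor.joint == joint, "rmse_mean"].iloc[0])
        report[f"{joint}_rmse_uncorrected_deg"] = round(r, 3)
        report[f"{joint}_rmse_corrected_deg"] = round(c, 3)
        print(f"{joint}: waveform RMSE {r:.2f} deg uncorrected -> {c:.2f} deg corrected")
    rom_diff = float(
        np.max(np.abs(raw["bias_rom"].values - cor["bias_rom"].values))
    )
    report["rom_bias_max_abs_change"] = rom_diff
    print(f"ROM bias change under correction: {rom_diff:.0e} (shift-invariant)")

    (OUT / "offset_bias_recovery.json").write_text(json.dumps(report, indent=2))
    print(f"wrote {OUT / 'offset_bias_recovery.json'}")


if __name__ == "__main__":
    main()
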