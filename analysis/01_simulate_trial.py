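#!/usr/bin/env python
"""Generate one synthetic trial and write its streams to plain-text files.

Demonstrates the data-generating process and the exchange formats: a
long-form keypoint CSV (one row per camera × frame × keypoint), a
two-column vertical-GRF CSV, the camera extrinsics as JSON, and the
ground-truth angle waveforms as a TRC-independent JSON record.
"""

import json
from pathlib import Path

import numpy as np

from gaitmmc.io import write_extrinsics, write_grf_table, write_keypoint_table
from gaitmmc.synth import Anthropometry, ObservationModel, default_gait_model, generate_trial

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    model = default_gait_model(1.0)
    trial = generate_trial(
        model,
        Anthropometry(),
        ObservationModel(seed=1),
        participant_id="P01",
        session=1,
        speed=1.0,
        duration=30.0,
        phase0=0.25,
    )

    write_keypoint_table(OUT / "keypoints_P01_s1.csv", list(trial.trial.markerless.values()))
    write_grf_table(OUT / "grf_P01_s1.csv", trial.trial.grf)
    write_extrinsics(OUT / "extrinsics.json", trial.extrinsics)
    truth = {
        "cycle_starts_s": [round(t, 6) for t in trial.truth_cycle_starts],
        "discrete_params_deg": trial.truth_params,
        "cycle_duration_s": trial.model.cycle_duration,
        "phase0": trial.phase0,
    }
    (OUT / "truth_P01_s1.json").write_text(json.dumps(truth, indent=2))

    n_frames = trial.trial.markerless["front"].n_frames
    print(f"wrote one 30 s trial to {OUT}")
    print(f"  3 cameras x {n_frames} frames at 30 Hz, GRF at 1000 Hz")
    print(f"  {len(trial.truth_cycle_starts)} ground-truth gait cycles")
    for joint, p in trial.truth_params.items():
        print(
            f"  true {joint}: max {p['max']:.1f} deg, min {p['min']:.1f} deg, "
            f"ROM {p['rom']:.1f} deg"
        )


if __name__ == "__main__":
    main()
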