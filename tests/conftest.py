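import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from gaitmmc.synth import (
    Anthropometry,
    ObservationModel,
    default_gait_model,
    generate_trial,
    generate_study,
)


@pytest.fixture(scope="session")
def noise_free_trial():
    """A 20 s trial at 1.0 m/s with every error mechanism switched off."""
    model = default_gait_model(1.0)
    obs = ObservationModel(keypoint_noise_sd=0.0, dropout_prob=0.0, seed=1)
    return generate_trial(
        model,
        Anthropometry(),
        obs,
        duration=20.0,
        phase0=0.3,
        reference_noise_sd_deg=0.0,
    )


@pytest.fixture(scope="session")
def small_study():
    """A reduced two-session study (5 participants, one speed) at defaults."""
    return generate_study(
        n_participants=5, sessions=2, speeds=(1.0,), seed=42, duration=25.0
    )


@pytest.fixture(scope="session")
def small_study_summaries(small_study):
    from gaitmmc.pipeline import summarize_study

    return summarize_study(small_study)
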