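import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cerebtfa import (  # noqa: E402
    CohortEffectConfig,
    SimulationConfig,
    TransferModel,
    simulate_cohort,
    simulate_map,
    simulate_mcav,
)


@pytest.fixture(scope="session")
def flat_template():
    """Constant gain 1.26 / phase 0.80 transfer model across all frequencies."""
    return TransferModel(
        kind="frequency_template",
        template=((0.01, 1.26, 0.80), (5.0, 1.26, 0.80)),
        mcav_setpoint=72.0,
    )


@pytest.fixture(scope="session")
def map_600s():
    """Default 600 s / 10 Hz MAP realisation (9 Welch segments)."""
    return simulate_map(SimulationConfig(duration=600.0, seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """3-subject cohort with zero phase scatter — fast end-to-end fixture."""
    effect = CohortEffectConfig(
        n_subjects=3,
        between_subject_sd=0.0,
        within_subject_sd=0.0,
        duration=600.0,
        seed=7,
    )
    return simulate_cohort(effect)
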