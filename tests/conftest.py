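import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fdbci import SyntheticConfig, TrialSet, generate_study

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_CFG = SyntheticConfig(
    n_channels=8,
    trials_per_class_per_session=24,
    trial_seconds=2.0,
    erd_channels=(1, 3, 5),
    seed=7,
)


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Desk-scale study configuration with the planted 8-12 Hz class effect."""
    return SMALL_CFG


@pytest.fixture(scope="session")
def small_study(small_cfg):
    """One generated (day1, day2) pair shared across tests (read-only)."""
    return generate_study(small_cfg)


def make_trialset(
    rng: np.random.Generator,
    n_trials: int = 8,
    n_channels: int = 3,
    n_samples: int = 500,
    fs: float = 250.0,
    session_id: str = "day1",
) -> TrialSet:
    """Plain white-noise trial set with balanced labels."""
    labels = np.arange(n_trials) % 2
    return TrialSet(
        data=rng.standard_normal((n_trials, n_channels, n_samples)),
        labels=labels,
        session_id=session_id,
        fs=fs,
    )
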