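import warnings

import pytest

from paintrial.config import TrialConfig, Trajectory
from paintrial.simulate import simulate_trial

warnings.filterwarnings("ignore", message="site")


@pytest.fixture(scope="session")
def small_config() -> TrialConfig:
    """A 2-site, 12-per-arm trial: fast but structurally complete."""
    return TrialConfig(n_per_arm=12, n_sites=2)


@pytest.fixture(scope="session")
def small_trial(small_config):
    return simulate_trial(small_config, seed=123)


@pytest.fixture(scope="session")
def default_trial():
    """One full-size trial under the default study conditions."""
    cfg = TrialConfig()
    return cfg, simulate_trial(cfg, seed=2024)


@pytest.fixture
def quiet_config() -> TrialConfig:
    """Noise-free, event-free configuration: scores equal the rounded arm
    trajectory and nothing interrupts follow-up."""
    return TrialConfig(
        n_per_arm=6,
        n_sites=1,
        between_subject_sd=0.0,
        within_subject_sd=0.0,
        site_sd=0.0,
        rescue_hazard_base=0.0,
        dropout_rates={},
        missing_hour0_prob=0.0,
        sporadic_missing_prob=0.0,
        major_deviation_prob=0.0,
        tramadol_only_prob=0.0,
    )
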