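import numpy as np
import pytest

from gaitwatch.synth_gait import GaitSimConfig, simulate_subject


@pytest.fixture
def clean_config() -> GaitSimConfig:
    """Noise-free, no between-subject variability: exact ground truth."""
    return GaitSimConfig(noise_sd_deg=0.0, subject_sd=0.0)


@pytest.fixture
def short_clean_config() -> GaitSimConfig:
    return GaitSimConfig(duration_s=4.0, noise_sd_deg=0.0, subject_sd=0.0)


@pytest.fixture
def default_config() -> GaitSimConfig:
    return GaitSimConfig()


@pytest.fixture
def clean_subject(clean_config):
    return simulate_subject(clean_config, seed=11, subject_id="clean")


def make_cohort(config, n, seed0, spec=None, prefix="s"):
    """n simulated landmark sequences with distinct subject ids."""
    return [
        simulate_subject(config, spec, seed=seed0 + i, subject_id=f"{prefix}{i:02d}")[0]
        for i in range(n)
    ]
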