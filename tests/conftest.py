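import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from echodim import PhantomConfig, StudyConfig, generate_study_tables

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def zero_noise_config(n_studies: int = 8, n_experts: int = 5) -> StudyConfig:
    """Study config with noiseless raters: annotations equal ground truth."""
    return StudyConfig(
        phantom=PhantomConfig(n_studies=n_studies, speckle_noise_sd=0.0),
        n_experts=n_experts,
        expert_longitudinal_sd_frac=0.0,
        expert_transverse_sd_frac=0.0,
        expert_sd_scale_range=(1.0, 1.0),
        expert_miss_prob=0.0,
        ai_longitudinal_sd_frac=0.0,
        ai_transverse_sd_frac=0.0,
        ai_miss_prob=0.0,
        render_images=False,
    )


def noisy_config(n_studies: int = 20, n_experts: int = 5) -> StudyConfig:
    """Moderate-noise config for statistical property tests."""
    return StudyConfig(
        phantom=PhantomConfig(n_studies=n_studies),
        n_experts=n_experts,
        expert_longitudinal_sd_frac=0.12,
        expert_transverse_sd_frac=0.06,
        expert_miss_prob=0.0,
        ai_longitudinal_sd_frac=0.10,
        ai_transverse_sd_frac=0.05,
        render_images=False,
    )


@pytest.fixture(scope="session")
def zero_noise_tables():
    return generate_study_tables(zero_noise_config(), seed=11, render_images=False)


@pytest.fixture(scope="session")
def noisy_tables():
    return generate_study_tables(noisy_config(), seed=7, render_images=False)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
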