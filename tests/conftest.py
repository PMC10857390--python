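import numpy as np
import pytest

from gaitforce import (
    ExperimentDesign,
    build_dataset,
    sample_subject,
    synthesize_gait_cycle,
)


@pytest.fixture(scope="session")
def young_subject():
    return sample_subject(seed=42, cohort="young")


@pytest.fixture(scope="session")
def elderly_subject():
    return sample_subject(seed=43, cohort="elderly")


@pytest.fixture(scope="session")
def clean_cycle(young_subject):
    """One noiseless gait cycle at medium speed."""
    return synthesize_gait_cycle(young_subject, speed=1.5, n_samples=100,
                                 seed=7)


@pytest.fixture(scope="session")
def tiny_dataset():
    """4 subjects x 3 cycles at one speed, noiseless, for fast pipeline
    tests."""
    design = ExperimentDesign(n_young=2, n_elderly=2,
                              cycles_per_subject_per_speed=3,
                              speeds=(1.5,), train_cycles_per_subject=2,
                              n_samples=100, seed=5)
    return build_dataset(design, angle_noise_sd=0.0,
                         velocity_noise_sd=0.0)


@pytest.fixture()
def rng():
    """Fresh seeded generator per test, so data is order-independent."""
    return np.random.default_rng(12345)
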