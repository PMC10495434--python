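import numpy as np
import pytest

from spinedyn import GeneratorConfig, generate_baseline_dataset, generate_stimulation_dataset


@pytest.fixture(scope="session")
def baseline_series():
    """A moderate activity-independent synthetic dataset (400 x 8)."""
    cfg = GeneratorConfig.for_cohort("activity_independent", seed=11, n_spines=400)
    return generate_baseline_dataset(cfg)


@pytest.fixture(scope="session")
def study_scale_series():
    """Full-scale spontaneous dataset (830 x 8)."""
    cfg = GeneratorConfig.for_cohort("activity_independent", seed=17)
    return generate_baseline_dataset(cfg)


@pytest.fixture(scope="session")
def stim_series():
    """A 15-spine stimulation cohort dataset."""
    return generate_stimulation_dataset(GeneratorConfig.for_cohort("stim15", seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
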