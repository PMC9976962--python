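import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from crossmeth.synth import (GeneratorConfig, generate_dataset,
                             generate_reference_profiles)


@pytest.fixture(scope="session")
def small_reference():
    return generate_reference_profiles(400, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_reference):
    config = GeneratorConfig(n_probes=400, n_studies=6, samples_per_study=30,
                             n_sex_dmps=20, seed=11)
    return generate_dataset(config, small_reference)


@pytest.fixture(scope="session")
def quiet_dataset():
    """Mild-noise compilation for parameter-recovery checks."""
    reference = generate_reference_profiles(300, seed=7)
    config = GeneratorConfig(n_probes=300, n_studies=4, samples_per_study=50,
                             noise_sd=0.1, study_offset_sd=0.4,
                             n_sex_dmps=10, sex_effect_delta=0.2, seed=7)
    return generate_dataset(config, reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
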