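import numpy as np
import pytest

from pulsespec.synthetic import (
    CohortConfig,
    SubjectSpec,
    default_base_profile,
    generate_recording,
)


@pytest.fixture(scope="session")
def base_profile():
    return default_base_profile()


@pytest.fixture(scope="session")
def still_profile():
    """Base profile with zero beat-to-beat dispersion."""
    return default_base_profile(amplitude_cv=0.0, phase_sd=0.0)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, wander-free study conditions."""
    return CohortConfig(noise_sd=0.0, baseline_wander_amp=0.0)


@pytest.fixture(scope="session")
def clean_subject(still_profile, clean_config):
    """One dispersion-free, noise-free subject: (recording, truth)."""
    spec = SubjectSpec("clean_000", "robust", "no_mets", 72.0, 0.0, still_profile)
    return generate_recording(spec, clean_config)


@pytest.fixture(scope="session")
def noisy_subject(base_profile):
    """One subject under the default study conditions."""
    spec = SubjectSpec("noisy_000", "robust", "no_mets", 72.0, 0.04, base_profile)
    return generate_recording(spec, CohortConfig())


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort for pipeline-level tests."""
    return CohortConfig(
        group_sizes={"robust": 9, "dynapenia": 3, "presarcopenia": 3, "sarcopenia": 3},
        duration_s=45.0,
        seed=5,
    )


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
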