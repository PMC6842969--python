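import numpy as np
import pytest

from plhfo import StudyConfig, analyze_case, generate_seizure_case, planted_config


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_case():
    """One planted-coupling seizure case (channels 0 and 1 coupled, resected)."""
    return generate_seizure_case(planted_config(seed=42))


@pytest.fixture(scope="session")
def planted_analysis(planted_case):
    """The full single-case analysis of the planted case, computed once."""
    return analyze_case(planted_case, StudyConfig())


def random_window(rng, n=500, scale=5.0):
    """A random (phi_lf, a_hfo, phi_hfo_env) triple of one analysis window."""
    phi = rng.uniform(-np.pi, np.pi, n)
    amp = scale * rng.gamma(2.0, 1.0, n)
    phi_env = rng.uniform(-np.pi, np.pi, n)
    return phi, amp, phi_env
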