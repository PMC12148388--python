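import numpy as np
import pytest

from paleoherd import (
    AnalysisConfig,
    SequenceSimParams,
    default_marker_db,
    simulate_tooth_sequence,
)


@pytest.fixture(scope="session")
def marker_db():
    return default_marker_db()


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture
def noiseless_sequence():
    """A clean cosine sequence with known parameters (A=1, x0=5, X=20, M=0)."""
    params = SequenceSimParams(
        A_true=1.0,
        M_true=0.0,
        X_true=20.0,
        birth_phase=0.25,
        n_samples=20,
        spacing=1.0,
        noise_sd=0.0,
    )
    return simulate_tooth_sequence(params)


def random_birth_params(rng: np.random.Generator, **overrides) -> SequenceSimParams:
    """Study-condition simulation parameters with a random birth phase."""
    defaults = dict(
        birth_phase=float(rng.random()),
        noise_sd=0.3,
        seed=int(rng.integers(2**31)),
    )
    defaults.update(overrides)
    return SequenceSimParams(**defaults)
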