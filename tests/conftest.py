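import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from entroprof.background import BackgroundModel
from entroprof.sequence import Sequence

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def uniform_m0() -> BackgroundModel:
    base = np.full(4, 0.25)
    return BackgroundModel(0, base, np.tile(base, (4, 1)), pseudocount=0.0)


@pytest.fixture
def skewed_m0() -> BackgroundModel:
    base = np.array([0.4, 0.3, 0.2, 0.1])
    return BackgroundModel(0, base, np.tile(base, (4, 1)), pseudocount=0.0)


@pytest.fixture
def stationary_m1() -> BackgroundModel:
    """Non-uniform first-order chain with its true stationary base vector.

    The closed-form moments assume a stationary chain, so the base
    distribution must be the left Perron eigenvector of the transitions.
    """
    pi = np.array(
        [
            [0.50, 0.20, 0.20, 0.10],
            [0.10, 0.40, 0.30, 0.20],
            [0.25, 0.25, 0.25, 0.25],
            [0.30, 0.10, 0.20, 0.40],
        ]
    )
    evals, evecs = np.linalg.eig(pi.T)
    stat = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
    stat = stat / stat.sum()
    return BackgroundModel(1, stat, pi, pseudocount=0.0)


def random_dna(rng: np.random.Generator, l: int, id: str = "seq") -> Sequence:
    return Sequence(id, "".join("ACGT"[c] for c in rng.integers(0, 4, l)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
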