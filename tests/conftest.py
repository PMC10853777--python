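import numpy as np
import pytest

from rtadte import QuantBundle


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_bundle(rng, T=10, n=2, B=5, fractional=True):
    counts = rng.uniform(0, 100, (T, n))
    if not fractional:
        counts = np.round(counts)
    return QuantBundle(
        transcript_ids=[f"TX{i:04d}" for i in range(T)],
        lengths=rng.integers(200, 3000, T),
        effective_lengths=rng.uniform(100, 2000, (T, n)),
        counts=counts,
        bootstraps=[rng.uniform(0, 100, (T, B)) for _ in range(n)],
        sample_ids=[f"s{j}" for j in range(n)],
    )


@pytest.fixture
def small_bundle(rng):
    return random_bundle(rng)


def poisson_bundle(rng, T=2000, n=4, B=100, lam=None):
    """Bootstraps drawn i.i.d. Poisson: true overdispersion is exactly 1."""
    if lam is None:
        lam = np.where(rng.random(T) < 0.5, 5.0, 50.0)
    boots = [rng.poisson(lam[:, None], (T, B)).astype(float) for _ in range(n)]
    return QuantBundle(
        transcript_ids=[f"TX{i:05d}" for i in range(T)],
        lengths=np.full(T, 1000),
        effective_lengths=np.full((T, n), 800.0),
        counts=np.tile(lam[:, None], (1, n)),
        bootstraps=boots,
        sample_ids=[f"s{j}" for j in range(n)],
    )
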