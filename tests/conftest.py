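import numpy as np
import pytest

from stareg import MixtureParams, MonotoneDensity, PairedPValues


def random_monotone_density(rng: np.random.Generator,
                            max_pieces: int = 6) -> MonotoneDensity:
    """A random valid non-increasing step density on [0, 1]."""
    k = rng.integers(1, max_pieces + 1)
    interior = np.sort(rng.uniform(0.05, 0.95, size=k - 1))
    knots = np.concatenate(([0.0], interior, [1.0]))
    heights = np.sort(rng.exponential(size=k))[::-1]
    heights = heights / np.sum(heights * np.diff(knots))
    return MonotoneDensity(knots=knots, heights=heights)


def random_mixture_params(rng: np.random.Generator) -> MixtureParams:
    xi = rng.dirichlet(np.ones(4))
    return MixtureParams(*xi)


def paired(p1, p2) -> PairedPValues:
    p1 = np.asarray(p1, dtype=float)
    ids = np.array([f"g{i}" for i in range(len(p1))])
    return PairedPValues(gene_ids=ids, p1=p1, p2=np.asarray(p2, dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
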