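import numpy as np
import pytest

from morphpro import ChainSpec, ScoreParams, generate_chain, make_morph_pair


@pytest.fixture(scope="session")
def params():
    return ScoreParams()


@pytest.fixture(scope="session")
def valid_chain():
    """A 30-residue protein-like chain (deterministic)."""
    return generate_chain(ChainSpec(n=30, seed=7))


@pytest.fixture(scope="session")
def small_chain():
    """A short chain cheap enough for the advanced strategy at full density."""
    return generate_chain(ChainSpec(n=6, seed=7))


@pytest.fixture(scope="session")
def hinge_pair():
    """Start/end traces related by a 25-degree hinge rotation."""
    return make_morph_pair(ChainSpec(n=24, seed=3), hinge_angle_deg=25.0)


def random_tiny_instance(rng, n=None, d_low=3.4, d_high=4.2):
    """A short random point sequence with near-bond consecutive spacing."""
    if n is None:
        n = int(rng.integers(2, 5))
    pts = [np.zeros(3)]
    for _ in range(n - 1):
        step = rng.uniform(d_low, d_high)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        pts.append(pts[-1] + step * v)
    return np.array(pts)
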