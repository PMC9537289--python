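import numpy as np
import pytest

from sfnet.connectome import make_variants
from sfnet.netmodel import LayerMatrix
from sfnet.synthetic import SyntheticSpec, generate_sc


def random_layer(
    rng: np.random.Generator,
    n: int,
    density: float = 0.5,
    binary: bool = False,
    allow_unnormalised: bool = False,
) -> LayerMatrix:
    """Random valid layer: symmetric, zero-diagonal, weights in [0, 1]."""
    iu = np.triu_indices(n, k=1)
    present = rng.random(iu[0].size) < density
    vals = np.ones(iu[0].size) if binary else rng.random(iu[0].size)
    w = np.zeros((n, n))
    w[iu] = np.where(present, vals, 0.0)
    w = w + w.T
    return LayerMatrix(w, allow_unnormalised=allow_unnormalised)


@pytest.fixture(scope="session")
def raw_sc() -> LayerMatrix:
    """Synthetic raw structural connectome at the study conditions."""
    return generate_sc(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def sc_variants(raw_sc):
    """The three cortical representations of the synthetic connectome."""
    return make_variants(raw_sc)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20231)


# small canonical graphs -----------------------------------------------------

@pytest.fixture()
def k3() -> LayerMatrix:
    return LayerMatrix(1.0 - np.eye(3))


@pytest.fixture()
def path3() -> LayerMatrix:
    return LayerMatrix(np.array([
        [0.0, 1.0, 0.0],
        [1.0, 0.0, 1.0],
        [0.0, 1.0, 0.0],
    ]))


@pytest.fixture()
def weighted_triangle() -> LayerMatrix:
    """Triangle with w01 = w02 = 0.5, w12 = 0.8."""
    return LayerMatrix(np.array([
        [0.0, 0.5, 0.5],
        [0.5, 0.0, 0.8],
        [0.5, 0.8, 0.0],
    ]))
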