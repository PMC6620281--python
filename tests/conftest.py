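import numpy as np
import pytest

from lsnquant import LICParams, LICState, PhantomSpec, Slice, generate_phantom
from lsnquant.segmentation import signed_distance_init


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, unbiased default phantom."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def ramp_phantom():
    """Planar-ramp bias (beta = 0.3) with 5%-of-contrast noise."""
    spec = PhantomSpec(seed=11, bias_kind="planar_ramp", bias_contrast=0.3,
                       noise_sd=0.05 * 110.0)
    return generate_phantom(spec)


@pytest.fixture
def tiny_problem():
    """An 8x8 image + state small enough for quadruple-loop oracles."""
    rng = np.random.default_rng(42)
    image = rng.uniform(0.0, 10.0, size=(8, 8))
    mask = np.zeros((8, 8), dtype=bool)
    mask[2:6, 2:6] = True
    phi = signed_distance_init(mask)
    bias = 1.0 + 0.2 * rng.uniform(-1.0, 1.0, size=(8, 8))
    params = LICParams(kernel_scale=1.5, length_weight=0.5,
                       regularization_weight=1.0, heaviside_width=1.0)
    state = LICState(phi=phi, bias=bias, cluster_means=(7.0, 2.0))
    return Slice(image), state, params
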