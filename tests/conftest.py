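import numpy as np
import pytest

from edgecrafting import compute_bin_grid
from edgecrafting.synthetic import (
    PlantedEdge,
    SyntheticSpec,
    default_spec,
    generate_gem,
)


@pytest.fixture(scope="session")
def grid38():
    """The default grid of the kidney-scale compendium: 38 x 38 bins."""
    return compute_bin_grid(18.89, 0.5)


@pytest.fixture(scope="session")
def grid19():
    return compute_bin_grid(18.89, 1.0)


@pytest.fixture(scope="session")
def small_gem():
    """12-gene GEM with 2 multimodal, 2 linear and 3 null planted pairs."""
    spec = default_spec(n_multimodal=2, n_linear=2, n_null=3, n_genes=12,
                        seed=11)
    return generate_gem(spec)


@pytest.fixture(scope="session")
def benchmark_gem():
    """The standard 100-gene benchmark (20/20/60 planted pairs)."""
    spec = default_spec(n_multimodal=20, n_linear=20, n_null=60, seed=1)
    return generate_gem(spec)


def gaussian_bump(n, centers, sigma, amplitude=1.0):
    """Sum of isotropic Gaussian bumps on an n x n image."""
    y, x = np.mgrid[0:n, 0:n]
    img = np.zeros((n, n))
    for r, c in centers:
        img += amplitude * np.exp(-((y - r) ** 2 + (x - c) ** 2)
                                  / (2 * sigma ** 2))
    return img
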