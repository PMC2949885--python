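import numpy as np
import pytest

from cellcarve.synthetic import SmearSpec, generate_smear


@pytest.fixture(scope="session")
def small_smear():
    """A 400 x 300 smear with 2 nuclei: fast enough for unit tests."""
    spec = SmearSpec(
        height=300, width=400, n_nuclei=2, nucleus_radius=(42.0, 50.0),
        n_red_cells=25, red_cell_radius=(16.0, 24.0), min_gap=25.0, seed=3,
    )
    image, truth = generate_smear(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def smear800():
    """One full-size 800 x 600 smear with 3 nuclei."""
    spec = SmearSpec(seed=7)
    image, truth = generate_smear(spec)
    return spec, image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
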