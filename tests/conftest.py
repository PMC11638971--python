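import numpy as np
import pytest

from crossfuse.datatypes import ModalityDataset
from crossfuse.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bimodal():
    """Moderate-linkage bimodal dataset with ground truth, reused read-only."""
    return generate(
        SyntheticSpec(n_cells=250, n_clusters=4, p_y=120, p_z=50, s_linked=20,
                      linkage_rho=0.8, noise_sd_y=0.3, noise_sd_z=0.3, seed=7)
    )


@pytest.fixture
def tiny_dataset():
    m = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
    return ModalityDataset(m, ["c0", "c1", "c2"], ["g1", "g2"])
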