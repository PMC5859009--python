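import numpy as np
import pytest

from xmerfish.codebook import assign_labels, generate_mhd4
from xmerfish.simulate import FieldGeometry, OpticsModel


@pytest.fixture(scope="session")
def codebook():
    """The unassigned 140-word MHD4 codebook."""
    return generate_mhd4(16)


@pytest.fixture(scope="session")
def assigned_codebook(codebook):
    """129 genes + 11 blanks on the full codebook (fixed seed)."""
    genes = [f"Gene-{i + 1:03d}" for i in range(129)]
    return assign_labels(codebook, genes, n_blanks=11, seed=0)


@pytest.fixture
def small_geometry():
    """20×20 µm single-section field on the standard 109-nm pixel grid."""
    return FieldGeometry(fov_x=20.0, fov_y=20.0)


@pytest.fixture
def quiet_optics():
    """Noise-free, constant-amplitude optics for deterministic constructions."""
    return OpticsModel(
        amplitude_cv=0.0,
        bit_cv=0.0,
        channel_gain=(1.0, 1.0),
        background=0.0,
        read_noise_sd=0.0,
        shot_noise=False,
        bead_count=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
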