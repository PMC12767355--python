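import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from junctionscope.graph import extract_graph
from junctionscope.mesh import make_mesh
from junctionscope.synth import generate_field, preset


@pytest.fixture(scope="session")
def small_mesh():
    """50-cell mesh in a 40x40 um field with a few higher-order vertices."""
    return make_mesh(50, (40, 40), seed=11, n_order4=6, n_order5=2)


@pytest.fixture(scope="session")
def small_graph(small_mesh):
    return extract_graph(small_mesh.label_image, small_mesh.pixel_size_um)


@pytest.fixture(scope="session")
def quiet_field():
    """Noise-free render with no gaps; polarity 3, TCJ enrichment 1.8."""
    cfg = preset("mutant_late", noise_sd=0.0, gap_prob_by_order={},
                 polarity_factor=3.0, tcj_enrichment=1.8)
    return generate_field(cfg, seed=21)


@pytest.fixture(scope="session")
def noisy_mutant_field():
    """A mutant_late field at the preset's own noise and gap statistics."""
    return generate_field(preset("mutant_late"), seed=22)


@pytest.fixture
def four_label_grid():
    """2x2 block grid: one central vertex where four cells meet."""
    L = np.zeros((20, 20), dtype=np.int32)
    L[:10, :10] = 1
    L[:10, 10:] = 2
    L[10:, :10] = 3
    L[10:, 10:] = 4
    return L
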