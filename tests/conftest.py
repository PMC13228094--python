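import numpy as np
import pytest

from emaconn.surface import make_surface
from emaconn.templates import make_templates


@pytest.fixture(scope="session")
def small_surface():
    """12x12 lattice with 4 mm^2 vertices (patches comfortably clear the
    30 mm^2 small-patch rule)."""
    return make_surface(12, 12, vertex_area=4.0)


@pytest.fixture(scope="session")
def small_templates(small_surface):
    templates, truth = make_templates(small_surface, K=4, seed=11)
    return templates, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
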