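import numpy as np
import pytest

from dermacontract.mesh import build_rect_mesh


@pytest.fixture(scope="session")
def mesh10():
    """Default coarse sensitivity-domain mesh (0.2 cm square, 10x10 cells)."""
    return build_rect_mesh(0.2, 0.2, 10, 10, 0.04, 0.04)


@pytest.fixture(scope="session")
def mesh_micro():
    """Comparison-domain mesh (120 x 80 um, 5 um spacing)."""
    return build_rect_mesh(120.0, 80.0, 24, 16, 40.0, 30.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
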