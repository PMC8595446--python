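import numpy as np
import pytest

from fistulaflow.fixtures import cylinder_tree
from fistulaflow.geometry import voxelize_vessels
from fistulaflow.units import UnitSystem


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def reference_units():
    """The reference blood discretisation (dx 50 um, dt 3 us)."""
    return UnitSystem(dx=50e-6, dt=3e-6)


@pytest.fixture(scope="session")
def small_cylinder_domain():
    """A small tube (R = 1 mm, L = 3 mm, dx = 0.2 mm) with inlet and outlet."""
    tree = cylinder_tree(radius=1.0e-3, length=3.0e-3)
    return voxelize_vessels(tree, dx=0.2e-3)
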