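import numpy as np
import pytest

from dtiabv.grids import Grid
from dtiabv.phantom import (PhantomSpec, StructureGeometry, build_tensor_phantom,
                            default_gradient_table, default_phantom,
                            straight_tract)


@pytest.fixture(scope="session")
def gtab():
    return default_gradient_table()


@pytest.fixture(scope="session")
def default_spec():
    return default_phantom()


@pytest.fixture(scope="session")
def default_anatomy(default_spec):
    return build_tensor_phantom(default_spec)


@pytest.fixture(scope="session")
def straight_spec():
    """Small phantom with one straight x-aligned tract and one structure."""
    grid = Grid((32, 24, 24), (2.0, 2.0, 2.0))
    c = (np.asarray(grid.shape) - 1) * 2.0 / 2.0
    return PhantomSpec(
        grid=grid,
        tracts=(straight_tract("rod", (8.0, c[1], c[2]), (56.0, c[1], c[2]), 6.0),),
        structures=(StructureGeometry("blob", 1, (c[0], c[1] + 10, c[2]), (7, 6, 6)),),
        brain_semi_axes_mm=(30.0, 22.0, 22.0),
    )


@pytest.fixture(scope="session")
def straight_anatomy(straight_spec):
    return build_tensor_phantom(straight_spec)
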