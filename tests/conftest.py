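import numpy as np
import pytest

from b0shim import (
    BrainMask,
    FieldMap,
    GridSpec,
    SubjectConfig,
    generate_subject,
)


@pytest.fixture(scope="session")
def coarse_grid():
    """Study grid at 2x the acquisition spacing (4.8 x 4.8 x 4 mm)."""
    return GridSpec().coarsened(2)


@pytest.fixture(scope="session")
def default_subject(coarse_grid):
    """One default synthetic subject on the coarse study grid."""
    return generate_subject(SubjectConfig(seed=0, grid=coarse_grid))


@pytest.fixture
def small_field():
    """Tiny deterministic field/mask pair for metric arithmetic tests."""
    rng = np.random.default_rng(7)
    data = rng.normal(0.0, 5.0, size=(10, 10, 10))
    fm = FieldMap(data, spacing=(2.4, 2.4, 2.0), origin=(0.0, 0.0, 0.0))
    mask = BrainMask(np.ones((10, 10, 10), bool), spacing=fm.spacing,
                     origin=fm.origin)
    return fm, mask
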