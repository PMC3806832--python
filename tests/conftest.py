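import numpy as np
import pytest

from ictalnet import forward as fw


@pytest.fixture(scope="session")
def head_model():
    return fw.HeadModel()


@pytest.fixture(scope="session")
def montage32(head_model):
    return fw.standard_1010_montage(32, head_model)


@pytest.fixture(scope="session")
def grid5(head_model):
    return fw.SourceGrid.for_model(head_model, 0.005)


@pytest.fixture(scope="session")
def leadfield(grid5, montage32, head_model):
    return fw.compute_leadfield(grid5, montage32, head_model)


@pytest.fixture(scope="session")
def leadfield_fn(montage32, head_model):
    return fw.make_leadfield_fn(montage32, head_model)


@pytest.fixture(scope="session")
def coarse_leadfield(head_model, montage32):
    """~3200-voxel grid at 7 mm, for whole-grid algebraic checks."""
    grid = fw.SourceGrid.for_model(head_model, 0.007)
    return fw.compute_leadfield(grid, montage32, head_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
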