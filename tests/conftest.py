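import numpy as np
import pytest

from watermbf import (
    InputFunctions,
    PhantomSpec,
    build_phantom,
    make_aif,
    make_basis,
    make_default_frame_schedule,
    make_rv_curve,
)


@pytest.fixture(scope="session")
def schedule():
    return make_default_frame_schedule()


@pytest.fixture(scope="session")
def inputs():
    aif = make_aif()
    return InputFunctions(c_a=aif, c_rv=make_rv_curve(aif))


@pytest.fixture(scope="session")
def basis(inputs, schedule):
    return make_basis(inputs, schedule)


def small_spec(**overrides) -> PhantomSpec:
    """A fast desk-scale phantom spec for unit tests (32^3 at 4 mm)."""
    defaults = dict(grid_shape=(32, 32, 32), voxel_size_mm=4.0, noise_scale=0.0)
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def noiseless_phantom():
    return build_phantom(small_spec())
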