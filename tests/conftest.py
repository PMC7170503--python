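import numpy as np
import pytest

import dwspect as dw


@pytest.fixture(scope="session")
def schedule():
    return dw.default_schedule()


@pytest.fixture(scope="session")
def grid():
    return dw.make_d_grid()


@pytest.fixture(scope="session")
def design(schedule, grid):
    return dw.build_design_matrix(schedule, grid)


@pytest.fixture(scope="session")
def two_compartment_mixture():
    return (dw.CompartmentSpec(D=1e-5, fraction=0.4),
            dw.CompartmentSpec(D=1e-3, fraction=0.6))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
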