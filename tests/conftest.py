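import numpy as np
import pytest

from hlecell import CellModel, CellParameters, build_reference_mesh


@pytest.fixture(scope="session")
def params():
    return CellParameters()


@pytest.fixture(scope="session")
def mesh(params):
    """Moderately coarse disc mesh shared by the unit tests."""
    return build_reference_mesh(params, target_edge=0.2)


@pytest.fixture(scope="session")
def model(params, mesh):
    return CellModel(params, mesh=mesh, n_phi=18)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_admissible_net(rng, scale=0.06):
    """Small random spline perturbation of the rest shape (never folds)."""
    from hlecell import ControlNet

    return ControlNet(rng.normal(scale=scale, size=(4, 4, 2)))
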