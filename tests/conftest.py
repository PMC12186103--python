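import numpy as np
import pytest

import sgtm
from sgtm.model import GTMModel, RBFBasis


def make_small_model(rng, n_dim=4, n_nodes=7, n_rbf=4, width=0.6, beta=2.0, reg=0.0):
    """Random small spherical model for oracle comparisons."""
    grid = sgtm.sphere_grid(n_nodes, n_rbf)
    basis = RBFBasis(grid.rbf_centers, width)
    w = rng.standard_normal((n_dim, n_rbf))
    return GTMModel(grid=grid, basis=basis, W=w, beta=beta, reg=reg,
                    data_mean=rng.standard_normal(n_dim))


def collapsed_model(n_nodes=6, n_dim=3, beta=1.0, mean=None):
    """Model whose every node maps to ``mean``: W = 0."""
    grid = sgtm.sphere_grid(n_nodes, 4)
    basis = RBFBasis(grid.rbf_centers, 0.5)
    mean = np.zeros(n_dim) if mean is None else np.asarray(mean, float)
    return GTMModel(grid=grid, basis=basis, W=np.zeros((n_dim, 4)), beta=beta,
                    reg=0.0, data_mean=mean)


@pytest.fixture(scope="session")
def p_orbital_cloud():
    return sgtm.make_p_orbital(1500, seed=11)


@pytest.fixture(scope="session")
def p_orbital_model(p_orbital_cloud):
    model, report = sgtm.fit(p_orbital_cloud.points, n_nodes=200, n_rbf=64,
                             width=0.3, reg=1.0, max_iter=80)
    return model, report
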