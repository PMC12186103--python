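import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import sgtm
from sgtm.geometry import sphere_grid
from sgtm.model import (
    FitConfig,
    GTMModel,
    RBFBasis,
    design_matrix,
    em_step,
    fit,
    log_likelihood,
    map_latent,
    parameter_scan,
    responsibilities,
)
from .conftest import collapsed_model, make_small_model


def naive_log_likelihood(model, X):
    """Direct double-loop evaluation of the node-mixture likelihood."""
    y = model.mapped_nodes
    k = y.shape[0]
    d = X.shape[1]
    out = []
    for x in X:
        s = 0.0
        for yk in y:
            s += math.exp(-model.beta * float(np.sum((x - yk) ** 2)))
        out.append(math.log(s / k) + 0.5 * d * math.log(model.beta / math.pi))
    return float(np.mean(out))


def naive_responsibilities(model, X):
    y = model.mapped_nodes
    r = np.empty((X.shape[0], y.shape[0]))
    for n, x in enumerate(X):
        for k, yk in enumerate(y):
            r[n, k] = math.exp(-model.beta * float(np.sum((x - yk) ** 2)))
        r[n] /= r[n].sum()
    return r


class TestDesignMatrix:
    def test_center_scores_one_and_width_scales(self):
        grid = sphere_grid(20, 5)
        basis = RBFBasis(grid.rbf_centers, 0.37)
        phi = design_matrix(grid.rbf_centers, basis, grid)
        np.testing.assert_allclose(np.diag(phi), 1.0, atol=1e-15)

    def test_value_at_one_sigma_and_at_pi(self):
        # two latent points at a chosen geodesic angle apart
        grid = sgtm.LatentGrid(
            kind="sphere",
            nodes=np.array([[np.pi / 2, 0.0]]),
            rbf_centers=np.array([[np.pi / 2, 0.3], [np.pi / 2, 0.0],
                                  [0.0, 0.0], [np.pi, 0.0]]),
        )
        basis = RBFBasis(grid.rbf_centers, width=0.3)
        phi = design_matrix(np.array([[np.pi / 2, 0.0]]), basis, grid)
        assert phi[0, 0] == pytest.approx(np.exp(-0.5), rel=1e-12)  # one sigma away
        pole = sgtm.LatentGrid(
            kind="sphere", nodes=grid.nodes,
            rbf_centers=np.array([[np.pi, 0.0]] * 4),
        )
        basis = RBFBasis(pole.rbf_centers, width=0.2)
        phi = design_matrix(np.array([[0.0, 0.0]]), basis, pole)
        assert phi[0, 0] == pytest.approx(np.exp(-np.pi**2 / 0.08), rel=1e-10)

    def test_flat_grid_uses_euclidean_distance(self):
        grid = sgtm.flat_grid(3, 2)
        basis = RBFBasis(grid.rbf_centers, 0.5)
        phi = design_matrix(np.array([[-1.0, -1.0]]), basis, grid)
        assert phi[0, 0] == pytest.approx(1.0)
        assert phi[0, 3] == pytest.approx(np.exp(-8.0 / 0.5))  # opposite corner, d^2=8

    def test_rejects_non_positive_width(self):
        grid = sphere_grid(10, 4)
        with pytest.raises(ValueError):
            RBFBasis(grid.rbf_centers, 0.0)


class TestMapLatent:
    def test_zero_weights_map_everything_to_mean(self):
        model = collapsed_model(mean=np.array([1.0, -2.0, 0.5]))
        out = map_latent(model, model.grid.nodes)
        np.testing.assert_allclose(out, np.tile(model.data_mean, (6, 1)), atol=1e-15)

    def test_matches_per_element_dot_products(self):
        rng = np.random.default_rng(5)
        model = make_small_model(rng, n_dim=3, n_nodes=9, n_rbf=5)
        pts = model.grid.nodes[:5]
        phi = design_matrix(pts, model.basis, model.grid)
        expected = np.array(
            [[sum(model.W[d, l] * phi[j, l] for l in range(5)) + model.data_mean[d]
              for d in range(3)] for j in range(5)]
        )
        np.testing.assert_allclose(map_latent(model, pts), expected, atol=1e-12)


class TestLikelihoodAndResponsibilities:
    def test_single_node_at_datum_closed_form(self):
        # one mixture component sitting exactly on x: LL = (D/2) log(beta/pi)
        grid = sgtm.LatentGrid(kind="sphere", nodes=np.array([[np.pi / 2, 0.0]]),
                               rbf_centers=np.column_stack(sgtm.fibonacci_grid(4)))
        model = GTMModel(grid=grid, basis=RBFBasis(grid.rbf_centers, 0.5),
                         W=np.zeros((3, 4)), beta=1.0, reg=0.0, data_mean=np.zeros(3))
        ll = log_likelihood(model, np.zeros((1, 3)))
        assert ll == pytest.approx(1.5 * math.log(1.0 / math.pi), rel=1e-12)

    def test_equidistant_nodes_average_away(self):
        # K nodes all at distance d from x score like a single node at d
        model = collapsed_model(n_nodes=6, beta=0.7)
        x = np.array([[0.3, -0.4, 1.0]])
        d2 = float(np.sum(x**2))
        expected = 1.5 * math.log(0.7 / math.pi) - 0.7 * d2
        assert log_likelihood(model, x) == pytest.approx(expected, rel=1e-12)
        r = responsibilities(model, x)
        np.testing.assert_allclose(r, 1.0 / 6.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_oracles(self, seed):
        rng = np.random.default_rng(seed)
        model = make_small_model(rng, n_dim=4, n_nodes=7, n_rbf=4, beta=1.3)
        X = rng.standard_normal((20, 4))
        assert log_likelihood(model, X) == pytest.approx(
            naive_log_likelihood(model, X), abs=1e-10)
        np.testing.assert_allclose(
            responsibilities(model, X), naive_responsibilities(model, X), atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        model = make_small_model(rng, beta=50.0)
        r = responsibilities(model, rng.standard_normal((40, 4)))
        np.testing.assert_allclose(r.sum(axis=1), 1.0, atol=1e-12)

    def test_sharp_beta_concentrates_on_nearest_node(self):
        rng = np.random.default_rng(2)
        model = make_small_model(rng, n_dim=3, beta=1.0)
        model = replace(model, beta=1e6, _cache=dict(model._cache))
        x = model.mapped_nodes[3] + 1e-3
        r = responsibilities(model, x[None, :])
        assert r[0, 3] > 1 - 1e-9

    def test_argument_errors(self):
        model = collapsed_model()
        with pytest.raises(ValueError):
            log_likelihood(model, np.empty((0, 3)))
        with pytest.raises(ValueError):
            log_likelihood(model, np.ones((2, 5)))
        with pytest.raises(ValueError):
            GTMModel(grid=model.grid, basis=model.basis, W=model.W, beta=-1.0,
                     reg=0.0, data_mean=model.data_mean)

    def test_flat_and_sphere_models_score_identically_when_nodes_coincide(self):
        """Likelihood sees only mapped node positions, never the latent kind."""
        mean = np.array([0.2, 0.4, -0.1])
        sph = collapsed_model(n_nodes=9, beta=1.1, mean=mean)
        flat_grid_ = sgtm.flat_grid(3, 2)
        flat = GTMModel(grid=flat_grid_, basis=RBFBasis(flat_grid_.rbf_centers, 0.5),
                        W=np.zeros((3, 4)), beta=1.1, reg=0.0, data_mean=mean)
        X = np.random.default_rng(0).standard_normal((25, 3))
        assert log_likelihood(sph, X) == log_likelihood(flat, X)


class TestEMStep:
    def test_likelihood_never_decreases_without_regularization(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((80, 3))
        model, _ = fit(X, n_nodes=36, n_rbf=9, width=0.6, reg=0.0, max_iter=0, tol=np.inf)
        ll = log_likelihood(model, X)
        for _ in range(50):
            model = em_step(model, X)
            ll_new = log_likelihood(model, X)
            assert ll_new >= ll - 1e-8
            ll = ll_new

    def test_self_consistent_data_is_a_fixed_point(self):
        # data placed exactly at the mapped nodes: W stays put, beta grows
        rng = np.random.default_rng(3)
        model = make_small_model(rng, n_dim=3, n_nodes=16, n_rbf=6, width=0.8, beta=200.0)
        X = model.mapped_nodes.copy()
        stepped = em_step(model, X)
        assert np.abs(stepped.W - model.W).max() < 1e-8
        assert stepped.beta > model.beta

    def test_huge_regularization_collapses_weights(self):
        rng = np.random.default_rng(4)
        model = make_small_model(rng, n_dim=3, n_nodes=16, n_rbf=6, beta=1.0, reg=1e9)
        stepped = em_step(model, rng.standard_normal((60, 3)))
        assert np.linalg.norm(stepped.W) < 1e-6


class TestFit:
    def test_recovers_noisy_sphere(self):
        cloud = sgtm.make_spherical_shell(600, noise=0.05, seed=2)
        model, report = fit(cloud.points, n_nodes=200, n_rbf=49, width=0.3,
                            reg=0.5, max_iter=100)
        radii = np.linalg.norm(model.mapped_nodes - cloud.points.mean(axis=0), axis=1)
        assert np.mean(np.abs(radii - 1.0)) < 3 * 0.05
        assert np.all(np.diff(report.log_likelihood_trace) > -1e-8)

    def test_duplicating_rows_changes_nothing_at_l_zero(self):
        X = sgtm.make_spherical_shell(200, seed=3).points
        m1, _ = fit(X, n_nodes=64, n_rbf=16, width=0.5, reg=0.0, max_iter=30)
        m2, _ = fit(np.vstack([X, X]), n_nodes=64, n_rbf=16, width=0.5, reg=0.0,
                    max_iter=30)
        assert np.abs(m1.W - m2.W).max() < 1e-10

    def test_infinite_tolerance_returns_initialization(self):
        X = np.random.default_rng(0).standard_normal((50, 3))
        _, report = fit(X, n_nodes=25, n_rbf=9, width=0.5, reg=1.0, tol=np.inf)
        assert report.iterations == 0
        assert report.converged

    def test_rejects_non_finite_data(self):
        X = np.ones((10, 3))
        X[3, 1] = np.nan
        with pytest.raises(ValueError):
            fit(X, n_nodes=16, n_rbf=4)

    def test_fit_is_deterministic(self):
        X = sgtm.make_ring_density(300, seed=9).points
        m1, r1 = fit(X, n_nodes=100, n_rbf=25, width=0.4, reg=1.0, max_iter=40)
        m2, r2 = fit(X, n_nodes=100, n_rbf=25, width=0.4, reg=1.0, max_iter=40)
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(r1.log_likelihood_trace, r2.log_likelihood_trace)

    def test_rotation_equivariance_of_mean_likelihood(self):
        # rotation small enough to preserve the PCA sign convention, so the
        # whole fit (init + EM) is exactly equivariant
        X = sgtm.make_p_orbital(400, seed=6).points
        rot = Rotation.from_rotvec([0.1, 0.2, -0.15]).as_matrix()
        kw = dict(n_nodes=100, n_rbf=25, width=0.4, reg=0.5, max_iter=60)
        _, r1 = fit(X, **kw)
        _, r2 = fit(X @ rot.T, **kw)
        assert r1.final_log_likelihood == pytest.approx(
            r2.final_log_likelihood, abs=1e-6)

    def test_flat_config_requires_square_counts(self):
        with pytest.raises(ValueError):
            FitConfig(kind="flat", n_nodes=10, n_rbf=4).build_grid()


class TestParameterScan:
    def test_single_configuration_table(self):
        cloud = sgtm.make_ring_density(240, seed=1)
        base = FitConfig(n_nodes=64, max_iter=20)
        table, best = parameter_scan(cloud.points[0::2], cloud.points[1::2],
                                     [16], [1.0], [0.4], base)
        assert len(table) == 1
        assert (best.n_rbf, best.reg, best.width) == (16, 1.0, 0.4)

    def test_empty_grid_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 3))
        with pytest.raises(ValueError):
            parameter_scan(X, X, [], [1.0], [0.2])

    def test_capacity_grows_with_m(self):
        """More RBF centers raise the frame likelihood on structured data."""
        cloud = sgtm.make_ring_density(600, seed=4)
        base = FitConfig(n_nodes=144, max_iter=60)
        table, _ = parameter_scan(cloud.points[0::2], cloud.points[1::2],
                                  [16, 64], [1.0], [0.3], base)
        by_m = table.set_index("m")["frame_ll"]
        assert by_m[64] > by_m[16]

    def test_over_regularization_not_selected(self):
        """Validation likelihood peaks below the heaviest smoothing."""
        cloud = sgtm.make_ring_density(600, seed=5)
        base = FitConfig(n_nodes=144, n_rbf=49, max_iter=60)
        table, best = parameter_scan(cloud.points[0::2], cloud.points[1::2],
                                     [49], [0.3, 1.0, 100.0], [0.3], base)
        assert best.reg != 100.0
        worst = table.set_index("l")["valid_ll"]
        assert worst[100.0] < worst.drop(100.0).max()
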