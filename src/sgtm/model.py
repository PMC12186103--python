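"""Shared GTM machinery for the flat and spherical variants.

The generative model is a constrained Gaussian mixture: K latent sample
points ("nodes") ``u_k`` on the latent surface are pushed through an RBF
network ``y(u) = W Phi(u) + mean`` into data space, and each mapped node
carries an isotropic density ``(beta/pi)^(D/2) exp(-beta ||x - y_k||^2)``
with uniform 1/K priors.  The two variants differ *only* in the latent
geometry (sphere with geodesic RBF distances vs. bounded square with
Euclidean ones); every likelihood-side computation below operates on the
mapped node positions alone, so mean log-likelihoods of the two variants
on the same data are directly comparable.

Fitting maximizes the mean per-point log-likelihood by
expectation-maximization; the M-step is a ridge-regularized weighted
least-squares solve, and the shape parameter ``beta`` is updated in
closed form.  No randomness is used anywhere in fitting, so fits are
bit-for-bit reproducible given the data and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from .geometry import LatentGrid, flat_grid, sphere_grid

__all__ = [
    "NumericalError",
    "RBFBasis",
    "GTMModel",
    "FitReport",
    "FitConfig",
    "design_matrix",
    "map_latent",
    "log_likelihood",
    "responsibilities",
    "em_step",
    "fit",
    "parameter_scan",
]


class NumericalError(RuntimeError):
    """Linear algebra failed during fitting (typically an unregularized,
    rank-deficient M-step system)."""


@dataclass(frozen=True)
class RBFBasis:
    """Gaussian radial basis set on the latent surface.

    All L basis functions share one width ``sigma`` (the tunable *w*),
    measured in geodesic radians on the sphere and in latent coordinate
    units on the flat square.
    """

    centers: np.ndarray  # (L, 2) latent points, same convention as the grid
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"RBF width must be positive, got {self.width!r}")
        object.__setattr__(self, "centers", np.atleast_2d(np.asarray(self.centers, dtype=float)))
        if self.centers.shape[0] < 4:
            raise ValueError("at least 4 RBF centers are required")


def design_matrix(points: np.ndarray, basis: RBFBasis, grid: LatentGrid) -> np.ndarray:
    """Evaluate the RBF design matrix Phi at latent ``points``.

    Entry (j, c) is ``exp(-d(p_j, c)^2 / (2 sigma^2))`` where d is the
    latent-surface distance of ``grid.kind`` (geodesic angle on the
    sphere, Euclidean on the flat square).  Unnormalized: a point sitting
    on a center scores exactly 1.
    """
    d = grid.latent_distances(points, basis.centers)
    return np.exp(-(d * d) / (2.0 * basis.width**2))


@dataclass(frozen=True)
class GTMModel:
    """A fitted (or initialized) GTM/SGTM: latent grid, basis, weights.

    ``W`` is D x L and maps RBF activations to *centered* data space;
    ``data_mean`` is added back when mapping, implementing data centering.
    ``beta`` is the inverse squared-scale of the per-node isotropic
    normal (density ``exp(-beta d^2)``, i.e. variance 1/(2 beta) per
    dimension).  ``reg`` is the ridge coefficient *l* applied in the
    M-step.
    """

    grid: LatentGrid
    basis: RBFBasis
    W: np.ndarray
    beta: float
    reg: float
    data_mean: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        W = np.atleast_2d(np.asarray(self.W, dtype=float))
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "data_mean", np.asarray(self.data_mean, dtype=float).ravel())
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta!r}")
        if self.reg < 0:
            raise ValueError(f"regularization must be non-negative, got {self.reg!r}")
        if W.shape[1] != self.basis.centers.shape[0]:
            raise ValueError(
                f"W has {W.shape[1]} columns but the basis has "
                f"{self.basis.centers.shape[0]} centers"
            )
        if self.data_mean.shape[0] != W.shape[0]:
            raise ValueError("data_mean dimensionality does not match W rows")

    @property
    def n_dim(self) -> int:
        return self.W.shape[0]

    @property
    def phi_nodes(self) -> np.ndarray:
        """Design matrix at the node grid, (K, L); computed once."""
        if "phi_nodes" not in self._cache:
            self._cache["phi_nodes"] = design_matrix(self.grid.nodes, self.basis, self.grid)
        return self._cache["phi_nodes"]

    @property
    def mapped_nodes(self) -> np.ndarray:
        """Node images on the manifold, y_k = W Phi(u_k) + mean, (K, D)."""
        if "mapped_nodes" not in self._cache:
            self._cache["mapped_nodes"] = self.phi_nodes @ self.W.T + self.data_mean
        return self._cache["mapped_nodes"]


def map_latent(model: GTMModel, points: np.ndarray) -> np.ndarray:
    """Map latent points through the manifold function y(u) = W Phi(u) + mean."""
    phi = design_matrix(points, model.basis, model.grid)
    return phi @ model.W.T + model.data_mean


def _check_data(model: GTMModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        raise ValueError("empty data matrix")
    if X.shape[1] != model.n_dim:
        raise ValueError(
            f"data has {X.shape[1]} columns but the model maps into {model.n_dim} dimensions"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("data matrix contains non-finite values")
    return X


def _sq_distances(model: GTMModel, X: np.ndarray) -> np.ndarray:
    return cdist(X, model.mapped_nodes, metric="sqeuclidean")


def log_likelihood(model: GTMModel, X: np.ndarray) -> float:
    """Mean per-point log-likelihood of ``X`` under the node mixture.

    Per point: ``log[(1/K) sum_k (beta/pi)^(D/2) exp(-beta ||x - y_k||^2)]``,
    evaluated through log-sum-exp.  The formula never looks at the latent
    geometry, only at mapped node positions, so flat and spherical models
    are scored by the identical code path.
    """
    X = _check_data(model, X)
    d2 = _sq_distances(model, X)
    k = d2.shape[1]
    per_point = logsumexp(-model.beta * d2, axis=1) - np.log(k)
    per_point += 0.5 * model.n_dim * np.log(model.beta / np.pi)
    return float(np.mean(per_point))


def responsibilities(model: GTMModel, X: np.ndarray) -> np.ndarray:
    """Posterior node assignment, r_nk = softmax_k(-beta ||x_n - y_k||^2).

    Rows sum to one; computed with shifted exponentials for stability.
    """
    X = _check_data(model, X)
    a = -model.beta * _sq_distances(model, X)
    a -= a.max(axis=1, keepdims=True)
    r = np.exp(a)
    r /= r.sum(axis=1, keepdims=True)
    return r


def _solve_weights(
    phi: np.ndarray, g: np.ndarray, rhs: np.ndarray, ridge: float, reg: float
) -> np.ndarray:
    """Solve (Phi^T G Phi + ridge I) W^T = rhs for W (D x L)."""
    a = phi.T @ (g[:, None] * phi)
    a[np.diag_indices_from(a)] += ridge
    try:
        w_t = cho_solve(cho_factor(a), rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - depends on data
        raise NumericalError(
            "M-step normal equations are singular; increase the regularization "
            f"coefficient l (currently {reg})"
        ) from exc
    if not np.all(np.isfinite(w_t)):
        raise NumericalError(
            "M-step produced non-finite weights; increase the regularization "
            f"coefficient l (currently {reg})"
        )
    return w_t.T


def em_step(model: GTMModel, X: np.ndarray) -> GTMModel:
    """One EM sweep: responsibilities, ridge-regularized weight solve,
    closed-form beta update.

    M-step: ``(Phi^T G Phi + (l/beta) I) W_new^T = Phi^T R^T X_centered``
    with G the diagonal of responsibility column sums, then
    ``beta_new = N D / (2 sum_nk r_nk ||x_n - y_k^new||^2)``.  The data
    term is a sum over points while the ridge penalty is fixed, so the
    effective per-point smoothing of a given l weakens as the dataset
    grows (standard GTM MAP practice); with l = 0 the update — and hence
    the whole fit — is exactly invariant under duplicating the dataset.
    """
    X = _check_data(model, X)
    r = responsibilities(model, X)
    phi = model.phi_nodes
    g = r.sum(axis=0)
    rhs = phi.T @ (r.T @ (X - model.data_mean))
    w_new = _solve_weights(phi, g, rhs, model.reg / model.beta, model.reg)

    new = replace(model, W=w_new, _cache={})
    d2 = _sq_distances(new, X)
    total = float(np.sum(r * d2))
    n, d_dim = X.shape
    if total <= 0.0:
        # data sits exactly on the manifold; cap beta instead of dividing by 0
        beta_new = model.beta * 1e6
    else:
        beta_new = n * d_dim / (2.0 * total)
    return replace(new, beta=beta_new, _cache={"phi_nodes": phi, "mapped_nodes": new.mapped_nodes})


@dataclass(frozen=True)
class FitReport:
    """Optimization trace: mean log-likelihood per iteration (index 0 is
    the initialized model), iteration count, convergence flag, final beta."""

    log_likelihood_trace: np.ndarray
    iterations: int
    converged: bool
    final_beta: float

    @property
    def final_log_likelihood(self) -> float:
        return float(self.log_likelihood_trace[-1])


@dataclass(frozen=True)
class FitConfig:
    """Hyperparameters of one GTM/SGTM fit.

    ``kind``: "sphere" or "flat".  ``n_nodes``: K, the mixture size (a
    perfect square for flat grids).  ``n_rbf``: L, the user-facing capacity parameter *m*.
    ``width``: shared RBF width *w*.  ``reg``: regularization *l*.
    Defaults follow common practice for mid-sized point clouds: K = 500
    spherical nodes (22 x 22 = 484 flat), m = 80, w = 0.2, l = 1.
    """

    kind: str = "sphere"
    n_nodes: int = 500
    n_rbf: int = 80
    width: float = 0.2
    reg: float = 1.0
    max_iter: int = 500
    tol: float = 1e-5

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "flat"):
            raise ValueError(f"unknown grid kind {self.kind!r}")

    def build_grid(self) -> LatentGrid:
        if self.kind == "sphere":
            return sphere_grid(self.n_nodes, self.n_rbf)
        k = int(round(np.sqrt(self.n_nodes)))
        c = int(round(np.sqrt(self.n_rbf)))
        if k * k != self.n_nodes or c * c != self.n_rbf:
            raise ValueError(
                "flat grids require perfect-square node and RBF counts; "
                f"got n_nodes={self.n_nodes}, n_rbf={self.n_rbf}"
            )
        return flat_grid(k, c)


def fit(X: np.ndarray, config: FitConfig | None = None, **kwargs) -> tuple[GTMModel, FitReport]:
    """Fit a GTM or SGTM to a data matrix by EM.

    The model is initialized deterministically from the data's principal
    components (PCA ellipsoid on the sphere, PCA plane on the flat grid)
    and iterated until the relative change in mean log-likelihood drops
    below ``tol`` or ``max_iter`` is reached.  Returns the model and the
    per-iteration likelihood trace.
    """
    from . import initialization  # local import: initialization builds on this module

    if config is None:
        config = FitConfig(**kwargs)
    elif kwargs:
        config = replace(config, **kwargs)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("data matrix contains non-finite values")
    if X.shape[0] < 4:
        raise ValueError("need at least 4 data points to fit")

    grid = config.build_grid()
    basis = RBFBasis(centers=grid.rbf_centers, width=config.width)
    if config.kind == "sphere":
        model = initialization.ellipsoid_init(grid, basis, initialization.pca3(X), config.reg)
    else:
        model = initialization.plane_init(grid, basis, X, config.reg)
    model = initialization.init_beta(model, X)

    trace = [log_likelihood(model, X)]
    converged = False
    for _ in range(config.max_iter):
        if np.isinf(config.tol):
            converged = True  # degenerate tolerance: accept the initialization
            break
        model = em_step(model, X)
        trace.append(log_likelihood(model, X))
        delta = abs(trace[-1] - trace[-2])
        if delta < config.tol * max(1.0, abs(trace[-2])):
            converged = True
            break
    report = FitReport(
        log_likelihood_trace=np.asarray(trace),
        iterations=len(trace) - 1,
        converged=converged,
        final_beta=model.beta,
    )
    return model, report


def parameter_scan(
    frame: np.ndarray,
    validation: np.ndarray,
    m_values=(80,),
    l_values=(1.0,),
    w_values=(0.2,),
    base: FitConfig | None = None,
) -> tuple[pd.DataFrame, FitConfig]:
    """Grid-scan the three tunable parameters (m, l, w).

    One model is fitted on the frame set per (m, l, w) combination; frame
    and validation mean log-likelihoods are tabulated.  The best
    configuration maximizes validation likelihood, with ties broken by
    frame likelihood and then by the smaller m.
    """
    frame = np.atleast_2d(np.asarray(frame, dtype=float))
    validation = np.atleast_2d(np.asarray(validation, dtype=float))
    if frame.shape[1] != validation.shape[1]:
        raise ValueError("frame and validation sets must share dimensionality")
    m_values, l_values, w_values = list(m_values), list(l_values), list(w_values)
    if not m_values or not l_values or not w_values:
        raise ValueError("empty parameter grid")
    base = base or FitConfig()

    rows = []
    for m in m_values:
        for l in l_values:
            for w in w_values:
                cfg = replace(base, n_rbf=int(m), reg=float(l), width=float(w))
                model, report = fit(frame, cfg)
                rows.append(
                    {
                        "m": int(m),
                        "l": float(l),
                        "w": float(w),
                        "frame_ll": report.final_log_likelihood,
                        "valid_ll": log_likelihood(model, validation),
                        "iterations": report.iterations,
                    }
                )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        by=["valid_ll", "frame_ll", "m"], ascending=[False, False, True], kind="mergesort"
    )
    best = order.iloc[0]
    best_cfg = replace(base, n_rbf=int(best["m"]), reg=float(best["l"]), width=float(best["w"]))
    return table, best_cfg
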