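"""Deterministic PCA-based initialization of the manifold.

The spherical model starts from an ellipsoid aligned with the first
three principal components of the data: relative semi-axis lengths
``1 : lambda2/lambda1 : lambda3/lambda1`` (eigenvalue ratios, as for the
flat GTM's classical PCA initialization), scaled so the major semi-axis
spans two standard deviations along PC1.  The flat baseline starts from
the PCA plane of the first two components.  Both solve a ridge
least-squares problem so that the mapped nodes approximate the target
surface; both are deterministic, with each principal component's sign
fixed by making its largest-magnitude entry positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import LatentGrid
from .model import GTMModel, RBFBasis, _solve_weights, design_matrix

logger = logging.getLogger(__name__)

__all__ = ["PCAInit", "pca3", "ellipsoid_init", "plane_init", "init_beta"]


@dataclass(frozen=True)
class PCAInit:
    """Leading principal components of a dataset.

    ``eigenvalues`` are the data-space variances along the components,
    sorted descending; ``components`` is the orthonormal D x n_comp
    basis; ``mean`` the data centroid.
    """

    eigenvalues: np.ndarray
    components: np.ndarray
    mean: np.ndarray


def _pca(X: np.ndarray, n_comp: int) -> PCAInit:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if n < 4:
        raise ValueError("need at least 4 data points for PCA initialization")
    mean = X.mean(axis=0)
    # population covariance: the initialization is then invariant under
    # duplicating the dataset, matching the mean-likelihood objective
    cov = np.cov(X - mean, rowvar=False, bias=True)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_comp]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude entry of each component positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
    flip[flip == 0] = 1.0
    return PCAInit(eigenvalues=evals, components=evecs * flip, mean=mean)


def pca3(X: np.ndarray) -> PCAInit:
    """First three principal components of the data.

    Raises a dimensionality error for D < 3: the spherical initialization
    needs three independent directions — pad the data or use the flat
    variant instead.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 3:
        raise ValueError(
            f"spherical initialization needs D >= 3 but data has D = {X.shape[1]}; "
            "pad the data with zero columns or fit the flat variant"
        )
    return _pca(X, 3)


def _init_weights(
    grid: LatentGrid, basis: RBFBasis, targets_centered: np.ndarray, reg: float
) -> np.ndarray:
    """Ridge least-squares fit of W so that mapped nodes track the targets.

    Reuses the M-step solver with an identity responsibility pairing of
    nodes to targets.  With reg = 0 a tiny jitter keeps the Gram matrix
    factorizable (nearly collinear RBF activations are common at
    moderate widths).
    """
    phi = design_matrix(grid.nodes, basis, grid)
    ridge = reg if reg > 0 else 1e-10 * np.trace(phi.T @ phi) / phi.shape[1]
    w = _solve_weights(phi, np.ones(phi.shape[0]), phi.T @ targets_centered, ridge, reg)
    rms = float(np.sqrt(np.mean((phi @ w.T - targets_centered) ** 2)))
    logger.info("initialization least-squares residual RMS: %.6g", rms)
    return w


def ellipsoid_init(grid: LatentGrid, basis: RBFBasis, pca: PCAInit, reg: float) -> GTMModel:
    """Initialize a spherical model to a PCA-aligned ellipsoid.

    The node with unit-sphere direction (a, b, c) targets
    ``mean + s (a PC1 + (lambda2/lambda1) b PC2 + (lambda3/lambda1) c PC3)``
    with overall scale ``s = 2 sqrt(lambda1)`` so the major axis covers
    about 95% of a Gaussian cloud; EM corrects the arbitrary scale.
    """
    if grid.kind != "sphere":
        raise ValueError("ellipsoid initialization requires a spherical grid")
    lam = np.asarray(pca.eigenvalues, dtype=float)
    if lam[0] <= 0:
        raise ValueError("degenerate data: leading PCA eigenvalue is zero")
    ratios = np.array([1.0, lam[1] / lam[0], lam[2] / lam[0]])
    scale = 2.0 * np.sqrt(lam[0])
    directions = grid.cartesian_nodes  # (K, 3) unit vectors
    targets_centered = (directions * ratios) @ (scale * pca.components.T)
    w = _init_weights(grid, basis, targets_centered, reg)
    return GTMModel(grid=grid, basis=basis, W=w, beta=1.0, reg=reg, data_mean=pca.mean)


def plane_init(grid: LatentGrid, basis: RBFBasis, X: np.ndarray, reg: float) -> GTMModel:
    """Initialize a flat model to the PCA plane of the first two components,
    scaled to two standard deviations per axis — classical GTM practice."""
    if grid.kind != "flat":
        raise ValueError("plane initialization requires a flat grid")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("flat initialization needs D >= 2")
    pca = _pca(X, 2)
    scales = 2.0 * np.sqrt(np.clip(pca.eigenvalues, 0.0, None))
    targets_centered = (grid.nodes * scales) @ pca.components.T
    w = _init_weights(grid, basis, targets_centered, reg)
    return GTMModel(grid=grid, basis=basis, W=w, beta=1.0, reg=reg, data_mean=pca.mean)


def init_beta(model: GTMModel, X: np.ndarray) -> GTMModel:
    """Set beta from the data: 1 / mean squared distance to the nearest
    initial mapped node.  Scale-free and deterministic."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d2 = cdist(X, model.mapped_nodes, metric="sqeuclidean")
    mean_nearest = float(np.mean(d2.min(axis=1)))
    if mean_nearest <= 0:
        mean_nearest = 1e-12
    return replace(model, beta=1.0 / mean_nearest, _cache=dict(model._cache))
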