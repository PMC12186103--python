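"""Synthetic point-cloud generators.

These emulate, at desk scale, the statistical structure of the two kinds
of datasets the method is aimed at:

* electron-position clouds sampled from volumetric orbital/density
  fields — a signed two-lobe p-orbital analogue, a six-fold-symmetric
  aromatic-ring density, noisy spherical shells;
* clustered high-dimensional descriptor matrices mimicking an enumerated
  chemical library, with cluster centers living on a closed (sphere-like)
  or bounded (sheet-like) 2-surface embedded in D dimensions.

Every generator takes an integer seed and is reproducible given it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ScalarField

__all__ = [
    "LabeledCloud",
    "sample_scalar_field",
    "make_p_orbital",
    "make_ring_density",
    "make_spherical_shell",
    "make_chemspace",
]


@dataclass(frozen=True)
class LabeledCloud:
    """Points (n x D) with an aligned integer label per point (lobe sign
    -1/+1, cluster id, or 0 when unlabeled)."""

    points: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        if self.points.shape[0] != self.labels.shape[0]:
            raise ValueError("labels are not aligned with points")

    @property
    def n(self) -> int:
        return self.points.shape[0]


def sample_scalar_field(field: ScalarField, n: int, mode: str = "density",
                        seed: int = 0) -> LabeledCloud:
    """Draw electron-like positions from a volumetric field.

    A voxel is chosen with probability proportional to its value
    (``density`` mode, values must be non-negative) or to its squared
    value (``orbital`` mode, Born rule on a signed amplitude); the
    position is then uniform within the voxel.  Orbital mode labels each
    point with the sign of its voxel's amplitude.  Sampling is exact at
    voxel resolution.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    if mode not in ("density", "orbital"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    v = np.asarray(field.values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("field contains non-finite values")
    if mode == "density":
        if np.any(v < 0):
            raise ValueError("density mode requires a non-negative field")
        weights = v.ravel()
    else:
        weights = (v * v).ravel()
    total = weights.sum()
    if total <= 0:
        raise ValueError("field has no mass to sample from")
    rng = np.random.default_rng(seed)
    flat = rng.choice(weights.size, size=n, p=weights / total)
    ijk = np.column_stack(np.unravel_index(flat, v.shape))
    frac = rng.uniform(size=(n, 3))
    points = field.voxel_position(ijk, frac)
    if mode == "orbital":
        labels = np.sign(v.ravel()[flat]).astype(int)
    else:
        labels = np.zeros(n, dtype=int)
    return LabeledCloud(points=points, labels=labels)


def make_p_orbital(n: int, separation: float = 2.0, lobe_sigma: float = 0.5,
                   seed: int = 0) -> LabeledCloud:
    """Two-lobe p-orbital analogue (the shape of a water HOMO).

    Two isotropic 3D Gaussian lobes sit at +/- separation/2 on the z
    axis; the label is the lobe sign, mimicking the opposite parity of
    the wavefunction across the nodal plane.  Defaults (2 Angstrom
    separation, 0.5 Angstrom lobe width) give clearly split lobes with a
    low-density nodal region, as in a molecular p-type orbital.
    """
    if separation <= 0:
        raise ValueError("lobe separation must be positive")
    rng = np.random.default_rng(seed)
    labels = rng.choice([-1, 1], size=n)
    centers = np.zeros((n, 3))
    centers[:, 2] = labels * separation / 2.0
    points = centers + lobe_sigma * rng.standard_normal((n, 3))
    return LabeledCloud(points=points, labels=labels)


def make_ring_density(n: int, n_sites: int = 6, ring_radius: float = 1.4,
                      site_sigma: float = 0.35, seed: int = 0) -> LabeledCloud:
    """Planar ring of Gaussian sites (an aromatic-ring density analogue).

    ``n_sites`` isotropic 3D Gaussians sit at the vertices of a regular
    polygon in the z = 0 plane; the mixture is C_{n_sites}-symmetric in
    distribution.  Defaults mirror a benzene-like ring: 1.4 Angstrom
    site radius, 0.35 Angstrom site spread.  Labels are site indices.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 ring sites")
    rng = np.random.default_rng(seed)
    labels = rng.integers(n_sites, size=n)
    ang = 2.0 * np.pi * labels / n_sites
    centers = np.column_stack([ring_radius * np.cos(ang), ring_radius * np.sin(ang),
                               np.zeros(n)])
    points = centers + site_sigma * rng.standard_normal((n, 3))
    return LabeledCloud(points=points, labels=labels)


def make_spherical_shell(n: int, radius: float = 1.0, noise: float = 0.05,
                         seed: int = 0) -> LabeledCloud:
    """Noisy spherical shell in 3D: uniform directions, isotropic Gaussian
    displacement of scale ``noise`` — data with exactly the topology the
    spherical manifold assumes."""
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    points = radius * d + noise * rng.standard_normal((n, 3))
    return LabeledCloud(points=points, labels=np.zeros(n, dtype=int))


def make_chemspace(n: int, n_dim: int = 20, n_clusters: int = 8,
                   topology: str = "sphere_like", noise: float = 0.1,
                   seed: int = 0) -> LabeledCloud:
    """Clustered Gaussian mixture mimicking an enumerated chemical library.

    Cluster centers are placed on a closed 2-sphere of unit radius
    (``sphere_like``) or uniformly on a bounded plane patch
    (``sheet_like``), embedded into ``n_dim`` dimensions by a random
    orthonormal map; each point is its cluster center plus isotropic
    noise.  Labels are cluster ids.  The defaults — 20-dimensional
    space, 8 clusters, noise a tenth of the surface scale — stand in for
    a descriptor matrix of structural-analogue families.
    """
    if n_dim < 3:
        raise ValueError("need n_dim >= 3")
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    if topology not in ("sphere_like", "sheet_like"):
        raise ValueError(f"unknown topology {topology!r}")
    rng = np.random.default_rng(seed)
    if topology == "sphere_like":
        c = rng.standard_normal((n_clusters, 3))
        c /= np.linalg.norm(c, axis=1, keepdims=True)
        basis_dim = 3
    else:
        c = rng.uniform(-1.0, 1.0, size=(n_clusters, 2))
        basis_dim = 2
    q, _ = np.linalg.qr(rng.standard_normal((n_dim, basis_dim)))
    centers = c @ q.T
    labels = rng.integers(n_clusters, size=n)
    points = centers[labels] + noise * rng.standard_normal((n, n_dim))
    return LabeledCloud(points=points, labels=labels)
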