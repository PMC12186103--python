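"""Latent-surface geometry for GTM variants.

Two latent surfaces are supported:

* the unit 2-sphere, sampled by a Fibonacci generalized spiral — a
  quasi-regular point set that sidesteps the fact that only five regular
  grids exist on a sphere;
* the bounded square ``[-1, 1]^2``, sampled by a regular lattice — the
  latent domain of the classical (flat) GTM baseline.

Points on the sphere are handled both as (theta, phi) angle pairs (polar
angle ``theta`` in ``[0, pi]``, azimuth ``phi`` in ``[0, 2*pi)``) and as
Cartesian unit 3-vectors; distances on the sphere are geodesic
(great-circle) angles.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

GOLDEN_RATIO = (np.sqrt(5.0) + 1.0) / 2.0

__all__ = [
    "GOLDEN_RATIO",
    "LatentGrid",
    "fibonacci_grid",
    "flat_grid",
    "sphere_grid",
    "geodesic_angle",
    "to_cartesian",
    "from_cartesian",
    "canonicalize_angles",
]


def canonicalize_angles(theta: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clip ``theta`` into [0, pi] and wrap ``phi`` into [0, 2*pi).

    At the poles the azimuth is undefined; it is canonicalized to 0.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.mod(np.asarray(phi, dtype=float), 2.0 * np.pi)
    theta = np.clip(theta, 0.0, np.pi)
    at_pole = (theta == 0.0) | (theta == np.pi)
    phi = np.where(at_pole, 0.0, phi)
    return theta, phi


def to_cartesian(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Map spherical angles to unit vectors ``(sin t cos p, sin t sin p, cos t)``.

    Accepts scalars or arrays; returns an array of shape ``(..., 3)``.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1)


def from_cartesian(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`to_cartesian`; input need not be normalized.

    Raises ``ValueError`` on (near-)zero vectors.
    """
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v, axis=-1)
    if np.any(norm == 0.0):
        raise ValueError("cannot convert the zero vector to spherical angles")
    unit = v / norm[..., None]
    theta = np.arccos(np.clip(unit[..., 2], -1.0, 1.0))
    phi = np.arctan2(unit[..., 1], unit[..., 0])
    return canonicalize_angles(theta, phi)


def geodesic_angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Great-circle angle (radians in [0, pi]) between unit vectors.

    Broadcasts over leading axes; the dot product is clamped to [-1, 1]
    so antipodal round-off cannot produce NaN.
    """
    dot = np.sum(np.asarray(u, dtype=float) * np.asarray(v, dtype=float), axis=-1)
    return np.arccos(np.clip(dot, -1.0, 1.0))


def geodesic_angle_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise geodesic angles between two sets of unit vectors.

    ``a`` is (n, 3), ``b`` is (m, 3); returns (n, m).
    """
    dot = np.clip(np.asarray(a) @ np.asarray(b).T, -1.0, 1.0)
    return np.arccos(dot)


def fibonacci_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-regular spherical point set from the Fibonacci spiral.

    The i-th point (i = 1..n) sits at polar angle
    ``theta_i = arccos(1 - 2 i / n)`` and azimuth
    ``phi_i = 2 pi frac(golden_ratio * i)`` with ``frac(x) = x - floor(x)``.
    ``theta`` increases strictly with i; the last point is the exact south
    pole. Returns ``(theta, phi)`` arrays of length n.
    """
    if int(n) != n or n < 1:
        raise ValueError(f"grid size must be a positive integer, got {n!r}")
    n = int(n)
    i = np.arange(1, n + 1, dtype=float)
    theta = np.arccos(np.clip(1.0 - 2.0 * i / n, -1.0, 1.0))
    phi = 2.0 * np.pi * np.modf(GOLDEN_RATIO * i)[0]
    return canonicalize_angles(theta, phi)


@dataclass(frozen=True)
class LatentGrid:
    """Node and RBF-center placement on one latent surface.

    ``kind`` is ``"sphere"`` or ``"flat"``.  ``nodes`` holds the latent
    sample points at which mixture components are centered (K of them);
    ``rbf_centers`` the basis-function centers (L of them, L <= K in
    sensible configurations).  On the sphere both are stored as angle
    pairs ``(K, 2)`` / ``(L, 2)`` in (theta, phi) order; flat grids store
    2D coordinates in [-1, 1]^2 directly.
    """

    kind: str
    nodes: np.ndarray
    rbf_centers: np.ndarray
    _cartesian_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "flat"):
            raise ValueError(f"unknown grid kind {self.kind!r}")
        object.__setattr__(self, "nodes", np.atleast_2d(np.asarray(self.nodes, dtype=float)))
        object.__setattr__(
            self, "rbf_centers", np.atleast_2d(np.asarray(self.rbf_centers, dtype=float))
        )
        if self.nodes.shape[1] != 2 or self.rbf_centers.shape[1] != 2:
            raise ValueError("latent points must be 2-column arrays")
        if self.kind == "flat":
            for name, arr in (("nodes", self.nodes), ("rbf_centers", self.rbf_centers)):
                if np.any(np.abs(arr) > 1.0 + 1e-12):
                    raise ValueError(f"flat-grid {name} must lie within [-1, 1]^2")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_centers(self) -> int:
        return self.rbf_centers.shape[0]

    @property
    def cartesian_nodes(self) -> np.ndarray:
        """Nodes embedded for distance computation: (K, 3) unit vectors on
        the sphere, the (K, 2) coordinates themselves on the flat grid."""
        return self._embed("nodes", self.nodes)

    @property
    def cartesian_centers(self) -> np.ndarray:
        return self._embed("centers", self.rbf_centers)

    def _embed(self, key: str, pts: np.ndarray) -> np.ndarray:
        if key not in self._cartesian_cache:
            if self.kind == "sphere":
                self._cartesian_cache[key] = to_cartesian(pts[:, 0], pts[:, 1])
            else:
                self._cartesian_cache[key] = pts
        return self._cartesian_cache[key]

    def latent_distances(self, points: np.ndarray, centers: np.ndarray | None = None) -> np.ndarray:
        """Pairwise latent-surface distance of ``points`` to ``centers``
        (default: this grid's RBF centers): geodesic angle on the sphere,
        Euclidean distance on the flat square."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if centers is None:
            centers = self.rbf_centers
        centers = np.atleast_2d(np.asarray(centers, dtype=float))
        if self.kind == "sphere":
            a = to_cartesian(points[:, 0], points[:, 1])
            b = to_cartesian(centers[:, 0], centers[:, 1])
            return geodesic_angle_matrix(a, b)
        diff = points[:, None, :] - centers[None, :, :]
        return np.sqrt(np.sum(diff * diff, axis=-1))

    # -- serialization ----------------------------------------------------

    def to_table(self) -> str:
        """Delimited-text dump (index, theta/u, phi/v, x, y, z) of nodes and
        centers; byte-deterministic."""
        buf = io.StringIO()
        buf.write(f"# kind\t{self.kind}\n")
        for section, pts in (("node", self.nodes), ("center", self.rbf_centers)):
            emb = to_cartesian(pts[:, 0], pts[:, 1]) if self.kind == "sphere" else None
            for idx, p in enumerate(pts):
                xyz = emb[idx] if emb is not None else np.array([p[0], p[1], 0.0])
                cols = [section, str(idx)] + [format(v, ".17g") for v in (*p, *xyz)]
                buf.write("\t".join(cols) + "\n")
        return buf.getvalue()

    @classmethod
    def from_table(cls, text: str) -> "LatentGrid":
        kind = None
        nodes: list[list[float]] = []
        centers: list[list[float]] = []
        for line in text.splitlines():
            if not line.strip():
                continue
            if line.startswith("# kind"):
                kind = line.split("\t")[1].strip()
                continue
            parts = line.split("\t")
            dest = nodes if parts[0] == "node" else centers
            dest.append([float(parts[2]), float(parts[3])])
        if kind is None:
            raise ValueError("grid table is missing its '# kind' header line")
        return cls(kind=kind, nodes=np.array(nodes), rbf_centers=np.array(centers))


def sphere_grid(n_nodes: int, n_centers: int) -> LatentGrid:
    """Spherical latent grid: independent Fibonacci spirals for the K nodes
    and the L RBF centers."""
    if n_nodes < n_centers:
        raise ValueError(f"need at least as many nodes as RBF centers ({n_nodes} < {n_centers})")
    if n_centers < 4:
        raise ValueError("at least 4 RBF centers are required")
    nodes = np.column_stack(fibonacci_grid(n_nodes))
    centers = np.column_stack(fibonacci_grid(n_centers))
    return LatentGrid(kind="sphere", nodes=nodes, rbf_centers=centers)


def _square_lattice(k_per_side: int) -> np.ndarray:
    if int(k_per_side) != k_per_side or k_per_side < 2:
        raise ValueError(f"flat grid needs at least 2 points per side, got {k_per_side!r}")
    side = np.linspace(-1.0, 1.0, int(k_per_side))
    u, v = np.meshgrid(side, side, indexing="ij")
    return np.column_stack([u.ravel(), v.ravel()])


def flat_grid(k_per_side: int, centers_per_side: int | None = None) -> LatentGrid:
    """Regular k x k node lattice on [-1, 1]^2 with RBF centers on a
    (usually coarser) regular lattice — the classical-GTM latent layout."""
    nodes = _square_lattice(k_per_side)
    if centers_per_side is None:
        centers_per_side = max(2, int(round(np.sqrt(k_per_side))))
    centers = _square_lattice(centers_per_side)
    return LatentGrid(kind="flat", nodes=nodes, rbf_centers=centers)
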