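"""Map-side outputs of a fitted model.

A fitted spherical model yields three visual artifacts:

* the manifold itself, rendered as a triangle mesh embedded in data
  space (for 3D data) or on the unit map sphere;
* the unit-sphere projection: each data point's responsibility pattern
  is collapsed to its center of mass over the node positions on the
  unit sphere, then normalized back onto the sphere;
* an equirectangular 2D image of that sphere (azimuth phi on x, polar
  angle theta on y), in the latent frame inherited from the PCA-aligned
  initialization.

The density landscape (per-node cumulated responsibility) colors either
view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull

from .geometry import canonicalize_angles, from_cartesian, to_cartesian
from .model import GTMModel, responsibilities

__all__ = [
    "ProjectionMap",
    "TriangleMesh",
    "project_points",
    "equirectangular",
    "inverse_equirectangular",
    "manifold_mesh",
    "density_landscape",
    "node_adjacency",
    "occupied_nodes_connected",
    "hemisphere_split_accuracy",
]

DEGENERATE_NORM = 1e-6


@dataclass(frozen=True)
class ProjectionMap:
    """Per-point unit-sphere coordinates and their 2D image.

    ``sphere_points``: (N, 3) unit vectors (responsibility centers of
    mass, renormalized).  ``equirect``: (N, 2) with x = phi in [0, 2 pi)
    and y = theta in [0, pi].  ``degenerate``: flag per point where the
    center of mass nearly vanished (antipodally balanced responsibility)
    and the arg-max node was used instead.
    """

    sphere_points: np.ndarray
    equirect: np.ndarray
    degenerate: np.ndarray


@dataclass(frozen=True)
class TriangleMesh:
    """Closed triangle mesh over the model nodes."""

    vertices: np.ndarray  # (K, 3)
    faces: np.ndarray  # (F, 3) integer vertex indices

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges, each row (i, j) with i < j."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [0, 2]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    @property
    def euler_characteristic(self) -> int:
        return self.vertices.shape[0] - self.edges.shape[0] + self.faces.shape[0]


def _require_sphere(model: GTMModel) -> None:
    if model.grid.kind != "sphere":
        raise ValueError("this output is defined for spherical models only")


def project_points(model: GTMModel, X: np.ndarray) -> ProjectionMap:
    """Collapse each point's responsibility pattern to one map-sphere point.

    The center of mass c_n = sum_k r_nk u_k over unit-sphere node
    positions is renormalized onto the sphere.  If ||c_n|| < 1e-6 the
    pattern is antipodally balanced: the point is flagged degenerate and
    placed at its arg-max responsibility node (ties to the lowest index).
    """
    _require_sphere(model)
    r = responsibilities(model, X)
    u = model.grid.cartesian_nodes
    com = r @ u
    norms = np.linalg.norm(com, axis=1)
    degenerate = norms < DEGENERATE_NORM
    sphere = np.empty_like(com)
    ok = ~degenerate
    sphere[ok] = com[ok] / norms[ok, None]
    if np.any(degenerate):
        sphere[degenerate] = u[np.argmax(r[degenerate], axis=1)]
    theta, phi = from_cartesian(sphere)
    return ProjectionMap(
        sphere_points=sphere,
        equirect=np.column_stack([phi, theta]),
        degenerate=degenerate,
    )


def equirectangular(sphere_points: np.ndarray) -> np.ndarray:
    """Unit vectors -> (phi, theta) pairs with phi on x and theta on y."""
    theta, phi = from_cartesian(np.atleast_2d(sphere_points))
    return np.column_stack([phi, theta])


def inverse_equirectangular(coords: np.ndarray) -> np.ndarray:
    """(phi, theta) pairs -> unit vectors; inverse of :func:`equirectangular`
    away from the poles (where phi is canonicalized to 0)."""
    coords = np.atleast_2d(coords)
    theta, phi = canonicalize_angles(coords[:, 1], coords[:, 0])
    return to_cartesian(theta, phi)


def manifold_mesh(model: GTMModel) -> TriangleMesh:
    """Triangulate the node set of a spherical model.

    Adjacency comes from the convex hull of the unit-sphere node
    positions (equivalently the spherical Delaunay triangulation, which
    is deterministic given the grid).  Vertices are the mapped node
    positions y_k when the data space is 3D — the manifold as seen among
    the data — and the unit-sphere nodes otherwise (map-side mesh).
    """
    _require_sphere(model)
    u = model.grid.cartesian_nodes
    if u.shape[0] < 4:
        raise ValueError("need at least 4 nodes to build a closed mesh")
    hull = ConvexHull(u)
    faces = hull.simplices.astype(int)
    vertices = model.mapped_nodes if model.n_dim == 3 else u
    return TriangleMesh(vertices=np.asarray(vertices, dtype=float), faces=faces)


def density_landscape(model: GTMModel, X: np.ndarray) -> np.ndarray:
    """Cumulated responsibility per node (column sums of R); sums to N."""
    return responsibilities(model, X).sum(axis=0)


# -- node-graph analysis --------------------------------------------------


def node_adjacency(model: GTMModel) -> np.ndarray:
    """Undirected node-graph edges, (E, 2) index pairs.

    Spherical grids use the map-sphere triangulation; flat grids use the
    4-neighbor lattice graph.
    """
    if model.grid.kind == "sphere":
        u = model.grid.cartesian_nodes
        hull = ConvexHull(u)
        faces = hull.simplices
        e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [0, 2]]])
        return np.unique(np.sort(e, axis=1), axis=0)
    k = int(round(np.sqrt(model.grid.n_nodes)))
    idx = np.arange(k * k).reshape(k, k)
    horiz = np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()])
    vert = np.column_stack([idx[:-1, :].ravel(), idx[1:, :].ravel()])
    return np.vstack([horiz, vert])


def occupied_nodes_connected(model: GTMModel, X: np.ndarray) -> bool:
    """Whether the nodes claiming the points of ``X`` (by arg-max
    responsibility) form one connected component of the node graph.

    Diagnoses the border-splitting artifact: a contiguous data cluster
    whose projection lands on disjoint patches of the map comes back
    False.
    """
    r = responsibilities(model, X)
    occupied = np.unique(np.argmax(r, axis=1))
    if occupied.size <= 1:
        return True
    edges = node_adjacency(model)
    keep = np.isin(edges[:, 0], occupied) & np.isin(edges[:, 1], occupied)
    edges = edges[keep]
    remap = -np.ones(model.grid.n_nodes, dtype=int)
    remap[occupied] = np.arange(occupied.size)
    m = occupied.size
    if edges.size == 0:
        return m == 1
    graph = coo_matrix(
        (np.ones(edges.shape[0]), (remap[edges[:, 0]], remap[edges[:, 1]])), shape=(m, m)
    )
    n_comp, _ = connected_components(graph, directed=False)
    return n_comp == 1


def hemisphere_split_accuracy(sphere_points: np.ndarray, labels: np.ndarray) -> float:
    """Accuracy of the best hemisphere split of binary-labeled projections.

    The separating direction is the difference of per-class mean vectors;
    each point is classified by the sign of its dot product with it.
    Measures how cleanly two populations (e.g. orbital lobes of opposite
    sign) occupy opposite halves of the map sphere.
    """
    s = np.atleast_2d(np.asarray(sphere_points, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("hemisphere split requires exactly two label values")
    axis = s[labels == classes[1]].mean(axis=0) - s[labels == classes[0]].mean(axis=0)
    norm = np.linalg.norm(axis)
    if norm == 0:
        return 0.5
    pred = np.where(s @ (axis / norm) > 0, classes[1], classes[0])
    return float(np.mean(pred == labels))
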