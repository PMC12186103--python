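"""Readers and writers for the formats the tool touches.

* Gaussian cube volumetric files (read): carrier for sampled electron
  densities and orbitals.
* Delimited numeric matrices, TSV/CSV (read/write) plus a compressed
  NumPy ``.npz`` container: descriptor matrices and point clouds.
* Wavefront OBJ / ASCII PLY triangle meshes (write): manifold export.
* Projection and density-landscape tables (write).
* A single ``.npz`` model container holding everything needed to reload
  a fitted model losslessly.

All text writers use 17-significant-digit floats and a fixed column
order, so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import LatentGrid
from .model import FitReport, GTMModel, RBFBasis
from .projection import ProjectionMap, TriangleMesh

__all__ = [
    "BOHR_TO_ANGSTROM",
    "CubeParseError",
    "ScalarField",
    "read_cube",
    "read_matrix",
    "write_matrix",
    "write_mesh",
    "write_projection",
    "write_landscape",
    "save_model",
    "load_model",
]

#: CODATA conversion applied to cube files whose header voxel counts are
#: positive (the de-facto convention marking atomic units).
BOHR_TO_ANGSTROM = 0.529177210903

_FLOAT_FMT = ".17g"


class CubeParseError(ValueError):
    """Malformed Gaussian cube file; the message names the offending line."""


@dataclass(frozen=True)
class ScalarField:
    """Volumetric scalar field on a regular (possibly skewed) grid.

    ``origin`` (Angstrom) and ``axes`` (3 x 3 voxel step vectors,
    Angstrom per step) place voxel (i, j, k) at
    ``origin + i axes[0] + j axes[1] + k axes[2]``.  ``values`` has shape
    ``shape`` = (nx, ny, nz); densities are non-negative while orbital
    amplitudes are signed.  ``atoms`` records (atomic number, x, y, z).
    """

    origin: np.ndarray
    axes: np.ndarray
    values: np.ndarray
    atoms: np.ndarray
    is_orbital: bool = False

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_position(self, ijk: np.ndarray, frac: np.ndarray | None = None) -> np.ndarray:
        """Cartesian position of voxel corner ``ijk`` (+ fractional offset)."""
        ijk = np.asarray(ijk, dtype=float)
        if frac is not None:
            ijk = ijk + np.asarray(frac, dtype=float)
        return self.origin + ijk @ self.axes


def read_cube(path) -> ScalarField:
    """Parse a Gaussian cube file.

    Header: two comment lines; natoms + origin; three voxel-axis lines.
    Positive voxel counts mark atomic units (converted to Angstrom on
    read); a negative natoms marks an orbital cube carrying an extra
    MO-index line after the atom block.  Values are stored x-outer /
    z-inner, as written.
    """
    text = Path(path).read_text()
    lines = text.splitlines()

    def need(i: int) -> str:
        if i >= len(lines):
            raise CubeParseError(f"{path}: file truncated at line {i + 1}")
        return lines[i]

    try:
        head = need(2).split()
        natoms = int(head[0])
        origin = np.array([float(x) for x in head[1:4]])
    except (IndexError, ValueError) as exc:
        raise CubeParseError(f"{path}: bad natoms/origin header at line 3") from exc

    counts = np.empty(3, dtype=int)
    axes = np.empty((3, 3))
    for row in range(3):
        try:
            parts = need(3 + row).split()
            counts[row] = int(parts[0])
            axes[row] = [float(x) for x in parts[1:4]]
        except (IndexError, ValueError) as exc:
            raise CubeParseError(f"{path}: bad voxel-axis record at line {4 + row}") from exc
    if np.any(counts == 0):
        raise CubeParseError(f"{path}: zero voxel count in header")
    bohr_units = bool(np.all(counts > 0))
    shape = tuple(abs(int(c)) for c in counts)

    is_orbital = natoms < 0
    n_at = abs(natoms)
    atoms = np.empty((n_at, 4))
    for a in range(n_at):
        lineno = 6 + a
        try:
            parts = need(lineno).split()
            atoms[a] = [float(parts[0]), *map(float, parts[2:5])]
        except (IndexError, ValueError) as exc:
            raise CubeParseError(f"{path}: bad atom record at line {lineno + 1}") from exc

    cursor = 6 + n_at
    n_fields = 1
    if is_orbital:
        mo_tokens = need(cursor).split()
        try:
            n_fields = int(mo_tokens[0])
        except ValueError as exc:
            raise CubeParseError(f"{path}: bad MO-count line at line {cursor + 1}") from exc
        # MO indices may wrap onto further lines; consume until we have them
        have = len(mo_tokens) - 1
        cursor += 1
        while have < n_fields:
            have += len(need(cursor).split())
            cursor += 1
        if n_fields != 1:
            raise CubeParseError(
                f"{path}: multi-orbital cubes ({n_fields} fields) are not supported"
            )

    raw = " ".join(lines[cursor:]).split()
    expected = shape[0] * shape[1] * shape[2]
    if len(raw) < expected:
        raise CubeParseError(
            f"{path}: value block holds {len(raw)} numbers, expected {expected} "
            f"(short block begins after line {cursor})"
        )
    try:
        values = np.array([float(v) for v in raw[:expected]]).reshape(shape)
    except ValueError as exc:
        raise CubeParseError(f"{path}: non-numeric token in value block") from exc

    if bohr_units:
        origin = origin * BOHR_TO_ANGSTROM
        axes = axes * BOHR_TO_ANGSTROM
        atoms = atoms.copy()
        atoms[:, 1:] *= BOHR_TO_ANGSTROM
    if np.linalg.matrix_rank(axes) < 3:
        raise CubeParseError(f"{path}: singular voxel axes")
    return ScalarField(origin=origin, axes=axes, values=values, atoms=atoms, is_orbital=is_orbital)


# -- matrices -------------------------------------------------------------


def read_matrix(path, delimiter: str | None = None, has_header: bool | None = None,
                has_row_ids: bool | None = None) -> np.ndarray:
    """Read a numeric matrix from delimited text or an ``.npz`` container.

    ``delimiter=None`` splits on any whitespace, falling back to commas.
    ``has_header`` / ``has_row_ids`` default to auto-detection (a first
    line or first column that does not parse as numbers).  Ragged rows
    raise with the offending row number; zero-variance columns trigger a
    warning naming their indices.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return z["matrix"]
    rows: list[list[str]] = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if delimiter is None:
            if "," in line and "\t" not in line:
                fields = [f.strip() for f in line.split(",")]
            else:
                fields = line.split()
        else:
            fields = [f.strip() for f in line.split(delimiter)]
        rows.append(fields)
    if not rows:
        raise ValueError(f"{path}: no data rows")

    def numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    if has_header is None:
        has_header = not all(numeric(t) for t in rows[0])
    if has_header:
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: header but no data rows")
    if has_row_ids is None:
        has_row_ids = not all(numeric(r[0]) for r in rows)
    width = len(rows[0])
    data = []
    for i, r in enumerate(rows):
        if len(r) != width:
            raise ValueError(
                f"{path}: ragged row {i + 1}: {len(r)} fields where {width} were expected"
            )
        body = r[1:] if has_row_ids else r
        try:
            data.append([float(t) for t in body])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric value in row {i + 1}") from exc
    matrix = np.asarray(data, dtype=float)
    if matrix.shape[0] > 1:
        constant = np.where(np.ptp(matrix, axis=0) == 0.0)[0]
        if constant.size:
            warnings.warn(
                f"{path}: zero-variance column(s) at indices {constant.tolist()}",
                stacklevel=2,
            )
    return matrix


def write_matrix(matrix: np.ndarray, path, delimiter: str = "\t",
                 header: list[str] | None = None) -> None:
    """Write a matrix as delimited text (or ``.npz`` when so suffixed);
    17-significant-digit floats make text round trips bitwise lossless."""
    path = Path(path)
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if path.suffix == ".npz":
        np.savez_compressed(path, matrix=matrix)
        return
    with open(path, "w") as fh:
        if header is not None:
            fh.write(delimiter.join(header) + "\n")
        for row in matrix:
            fh.write(delimiter.join(format(v, _FLOAT_FMT) for v in row) + "\n")


# -- meshes and projections ----------------------------------------------


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = None) -> None:
    """Write a triangle mesh as Wavefront OBJ (1-based indices) or ASCII PLY."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    v, f = mesh.vertices, mesh.faces
    if fmt == "obj":
        with open(path, "w") as fh:
            for row in v:
                fh.write("v " + " ".join(format(x, _FLOAT_FMT) for x in row) + "\n")
            for tri in f:
                fh.write(f"f {tri[0] + 1} {tri[1] + 1} {tri[2] + 1}\n")
    elif fmt == "ply":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(v)}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            fh.write(f"element face {len(f)}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for row in v:
                fh.write(" ".join(format(x, _FLOAT_FMT) for x in row) + "\n")
            for tri in f:
                fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
    else:
        raise ValueError(f"unknown mesh format {fmt!r} (use 'obj' or 'ply')")


def write_projection(pmap: ProjectionMap, path) -> None:
    """Projection table: id, x(phi), y(theta), sphere xyz, degenerate flag."""
    with open(Path(path), "w") as fh:
        fh.write("id\tx\ty\tsx\tsy\tsz\tdegenerate\n")
        for i in range(pmap.sphere_points.shape[0]):
            vals = [pmap.equirect[i, 0], pmap.equirect[i, 1], *pmap.sphere_points[i]]
            cols = [str(i)] + [format(v, _FLOAT_FMT) for v in vals] + [str(int(pmap.degenerate[i]))]
            fh.write("\t".join(cols) + "\n")


def write_landscape(model: GTMModel, mass: np.ndarray, path) -> None:
    """Density-landscape table: node_id, theta/u, phi/v, cumulated mass."""
    nodes = model.grid.nodes
    with open(Path(path), "w") as fh:
        fh.write("node_id\ttheta\tphi\tmass\n")
        for i in range(nodes.shape[0]):
            cols = [str(i)] + [format(v, _FLOAT_FMT) for v in (*nodes[i], mass[i])]
            fh.write("\t".join(cols) + "\n")


# -- model container ------------------------------------------------------


def save_model(model: GTMModel, path, report: FitReport | None = None) -> None:
    """Serialize a model (and optionally its likelihood trace) to ``.npz``.

    The container stores the grid kind, node and RBF-center latent
    coordinates, W, beta, l, sigma, data mean and the trace; loading
    reconstructs the model losslessly.
    """
    trace = report.log_likelihood_trace if report is not None else np.empty(0)
    np.savez_compressed(
        Path(path),
        kind=np.array(model.grid.kind),
        nodes=model.grid.nodes,
        rbf_centers=model.grid.rbf_centers,
        width=np.array(model.basis.width),
        W=model.W,
        beta=np.array(model.beta),
        reg=np.array(model.reg),
        data_mean=model.data_mean,
        ll_trace=np.asarray(trace, dtype=float),
    )


def load_model(path) -> tuple[GTMModel, np.ndarray]:
    """Inverse of :func:`save_model`; returns (model, likelihood trace)."""
    with np.load(Path(path)) as z:
        grid = LatentGrid(kind=str(z["kind"]), nodes=z["nodes"], rbf_centers=z["rbf_centers"])
        basis = RBFBasis(centers=z["rbf_centers"], width=float(z["width"]))
        model = GTMModel(
            grid=grid,
            basis=basis,
            W=z["W"],
            beta=float(z["beta"]),
            reg=float(z["reg"]),
            data_mean=z["data_mean"],
        )
        return model, z["ll_trace"].copy()
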