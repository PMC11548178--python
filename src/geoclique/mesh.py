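"""Surface containers and I/O.

A :class:`TriangleMesh` is the carrier for everything downstream: geodesic
measurement, descriptor extraction, and registration all run against its
vertex/face arrays. Point clouds (XYZ files, faceless PLY) are carried in the
same container with an empty face list and ``is_meshed() == False``; they are
routed through :func:`knn_proxy_mesh` whenever edge connectivity is needed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "TriangleMesh",
    "FormatError",
    "InputError",
    "read_surface",
    "write_surface",
    "knn_proxy_mesh",
]


class FormatError(ValueError):
    """Raised when a surface file does not parse under its declared format."""


class InputError(ValueError):
    """Raised for structurally invalid inputs (empty vertex set, bad indices)."""


@dataclasses.dataclass
class TriangleMesh:
    """Triangle surface (or bare point set) in meters, 0-based indexing.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Empty for unmeshed point clouds.
    labels : (n,) int array, optional
        Per-vertex part identifiers (e.g. body-part segmentation).
    extra_edges : (k, 2) int array, optional
        Additional graph edges beyond face edges; used by the k-NN proxy
        so point clouds can share the geodesic machinery.
    """

    vertices: np.ndarray
    faces: np.ndarray
    labels: np.ndarray | None = None
    extra_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.vertices.shape[0] == 0:
            raise InputError("mesh has an empty vertex set")
        n = self.vertices.shape[0]
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= n:
                raise FormatError(
                    f"face index out of range [0, {n}): "
                    f"min={self.faces.min()}, max={self.faces.max()}"
                )
            a, b, c = self.faces.T
            if np.any((a == b) | (b == c) | (a == c)):
                raise FormatError("degenerate face with repeated vertex index")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != n:
                raise InputError("labels length does not match vertex count")

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    def is_meshed(self) -> bool:
        return self.faces.size > 0

    def edges(self) -> np.ndarray:
        """Unique undirected edges of the face graph plus any extra edges."""
        es = []
        if self.faces.size:
            f = self.faces
            es.append(np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]))
        if self.extra_edges is not None and len(self.extra_edges):
            es.append(np.asarray(self.extra_edges, dtype=np.int64))
        if not es:
            return np.empty((0, 2), dtype=np.int64)
        e = np.concatenate(es)
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def edge_graph(self) -> "coo_matrix":
        """Symmetric sparse adjacency weighted by Euclidean edge length."""
        e = self.edges()
        if len(e) == 0:
            n = self.n_vertices
            return coo_matrix((n, n))
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        n = self.n_vertices
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        data = np.concatenate([w, w])
        return coo_matrix((data, (rows, cols)), shape=(n, n))

    def is_connected(self) -> bool:
        ncomp, _ = connected_components(self.edge_graph().tocsr(), directed=False)
        return ncomp == 1

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    return path.suffix.lstrip(".").lower()


def read_surface(path: str | Path, format: str | None = None) -> TriangleMesh:
    """Read an OBJ/PLY/XYZ surface file.

    XYZ files and faceless PLY yield an unmeshed point cloud (empty faces).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    if fmt == "xyz":
        import warnings

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)  # empty-file notice
                pts = np.loadtxt(path, dtype=np.float64, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"cannot parse XYZ file {path}: {exc}") from exc
        if pts.size == 0:
            raise InputError(f"empty vertex set in {path}")
        if pts.shape[1] < 3:
            raise FormatError(f"XYZ rows need >= 3 columns, got {pts.shape[1]}")
        return TriangleMesh(pts[:, :3], np.empty((0, 3), dtype=np.int64))
    if fmt not in ("obj", "ply"):
        raise FormatError(f"unsupported surface format: {fmt!r}")
    try:
        loaded = trimesh.load(path, file_type=fmt, process=False)
    except Exception as exc:  # trimesh raises a zoo of types
        raise FormatError(f"cannot parse {fmt} file {path}: {exc}") from exc
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if not geoms:
            raise InputError(f"empty vertex set in {path}")
        loaded = geoms[0]
    verts = np.asarray(loaded.vertices, dtype=np.float64)
    if verts.size == 0:
        raise InputError(f"empty vertex set in {path}")
    faces = (
        np.asarray(loaded.faces, dtype=np.int64)
        if hasattr(loaded, "faces") and len(getattr(loaded, "faces", [])) > 0
        else np.empty((0, 3), dtype=np.int64)
    )
    return TriangleMesh(verts, faces)


def write_surface(mesh: TriangleMesh, path: str | Path, format: str | None = None) -> None:
    """Write OBJ or PLY (ascii); point clouds are written as vertex-only files."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "obj":
        with open(path, "w") as fh:
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            for f in mesh.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    elif fmt == "ply":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {mesh.n_vertices}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            fh.write(f"element face {len(mesh.faces)}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for v in mesh.vertices:
                fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    else:
        raise FormatError(f"unsupported output format: {fmt!r}")


def knn_proxy_mesh(points: np.ndarray, k: int = 8) -> TriangleMesh:
    """Symmetric k-NN graph over a point set, as a geodesic substrate.

    The returned object has no faces; connectivity lives in ``extra_edges``
    with Euclidean edge weights implied by vertex positions. Raises
    :class:`InputError` if the graph is disconnected at the chosen ``k``
    (the message names the largest component size).
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    n = len(points)
    if k < 3:
        raise InputError(f"k must be >= 3, got {k}")
    if n <= k:
        raise InputError(f"need more than k={k} points, got {n}")
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k + 1)  # first neighbor is the point itself
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    edges = np.sort(np.stack([rows, cols], axis=1), axis=1)
    edges = np.unique(edges, axis=0)
    mesh = TriangleMesh(points, np.empty((0, 3), dtype=np.int64), extra_edges=edges)
    ncomp, labels = connected_components(mesh.edge_graph().tocsr(), directed=False)
    if ncomp > 1:
        largest = int(np.bincount(labels).max())
        raise InputError(
            f"k-NN graph disconnected at k={k}: {ncomp} components, "
            f"largest has {largest} of {n} points"
        )
    return mesh
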