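"""Triangle-mesh data structures and geometry primitives.

A cortical surface is a closed 2-manifold triangle mesh in world millimetres.
Every per-vertex quantity downstream (intensity, thickness, GWR, statistic
maps) is indexed by the vertex set of such a mesh, so this module owns the
two containers the rest of the package shares: :class:`TriangleMesh` and
:class:`VertexMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "TriangleMesh",
    "VertexMap",
    "vertex_normals",
    "vertex_adjacency",
    "adjacency_matrix",
    "unique_edges",
    "mean_edge_length",
    "geodesic_distances",
]

#: faces with area below this (mm^2) are rejected as degenerate
DEGENERATE_AREA_TOL = 1e-12


class MeshError(ValueError):
    """Raised when a mesh violates its structural invariants."""


@dataclass(frozen=True)
class TriangleMesh:
    """A triangle mesh: ``vertices`` (n, 3) world mm, ``faces`` (m, 3) 0-based.

    Validation enforces index bounds, distinct face indices, and a minimum
    face area; closedness is checked on demand via :meth:`is_closed` because
    open patches are legitimate inputs for some operations.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshError(f"faces must be (m, 3), got {f.shape}")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise MeshError("face index out of range [0, n_vertices)")
        if f.size:
            if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])).any():
                raise MeshError("face with repeated vertex index")
            areas = _face_areas(v, f)
            bad = np.flatnonzero(areas < DEGENERATE_AREA_TOL)
            if bad.size:
                raise MeshError(
                    f"{bad.size} degenerate face(s) with area < {DEGENERATE_AREA_TOL} "
                    f"mm^2 (first: face {bad[0]})"
                )
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_closed(self) -> bool:
        """True iff every edge is shared by exactly two faces (2-manifold, closed)."""
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool((counts == 2).all())

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


@dataclass
class VertexMap:
    """One scalar per mesh vertex with an explicit missing mask.

    ``values`` entries under the mask are NaN-filled on construction so an
    accidental use of a missing value poisons the result loudly instead of
    biasing it silently.
    """

    values: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if self.missing is None:
            m = np.isnan(v)
        else:
            m = np.asarray(self.missing, dtype=bool).ravel() | np.isnan(v)
            if m.shape != v.shape:
                raise ValueError("missing mask length differs from values length")
        v = v.copy()
        v[m] = np.nan
        self.values = v
        self.missing = m

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[~self.missing]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "VertexMap":
        return VertexMap(values, name=self.name if name is None else name)


def _face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    p = vertices[faces]
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def face_normals(mesh: TriangleMesh, *, normalized: bool = True) -> np.ndarray:
    """Per-face normals; un-normalized length equals twice the face area."""
    p = mesh.vertices[mesh.faces]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    if normalized:
        n = n / np.linalg.norm(n, axis=1, keepdims=True)
    return n


def vertex_normals(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted per-vertex unit normals.

    The normal at a vertex is the sum of incident face normals weighted by
    face area (the raw cross products carry the weighting), renormalized.
    Orientation follows the face winding; for outward-wound closed meshes the
    normals point away from the enclosed volume.

    Returns
    -------
    normals : (n, 3) float array; rows of NaN where undefined.
    defined : (n,) bool mask, False for isolated vertices (no incident face).
    """
    weighted = face_normals(mesh, normalized=False)  # 2*area*unit normal
    acc = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], weighted)
    norms = np.linalg.norm(acc, axis=1)
    counts = np.zeros(mesh.n_vertices, dtype=np.int64)
    np.add.at(counts, mesh.faces.ravel(), 1)
    defined = (counts > 0) & (norms > 0)
    out = np.full_like(acc, np.nan)
    out[defined] = acc[defined] / norms[defined, None]
    return out, defined


def unique_edges(mesh: TriangleMesh) -> np.ndarray:
    """Sorted unique undirected edges, shape (n_edges, 2)."""
    e = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    return np.unique(e, axis=0)


def vertex_adjacency(mesh: TriangleMesh) -> list[np.ndarray]:
    """Neighbor lists: ``adj[v]`` holds every vertex sharing an edge with v."""
    edges = unique_edges(mesh)
    adj: list[list[int]] = [[] for _ in range(mesh.n_vertices)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    return [np.array(sorted(n), dtype=np.int64) for n in adj]


def adjacency_matrix(mesh: TriangleMesh, *, weighted: bool = False) -> sparse.csr_matrix:
    """Sparse symmetric adjacency; weights are edge lengths when ``weighted``."""
    edges = unique_edges(mesh)
    if weighted:
        w = np.linalg.norm(
            mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
        )
    else:
        w = np.ones(len(edges))
    n = mesh.n_vertices
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    data = np.concatenate([w, w])
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def mean_edge_length(mesh: TriangleMesh) -> float:
    """Arithmetic mean length over unique edges, in mm."""
    edges = unique_edges(mesh)
    lengths = np.linalg.norm(
        mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
    )
    return float(lengths.mean())


def geodesic_distances(mesh: TriangleMesh, source: int) -> np.ndarray:
    """Graph-geodesic distance (Dijkstra over edge lengths) from one vertex."""
    g = adjacency_matrix(mesh, weighted=True)
    return dijkstra(g, directed=False, indices=source)
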