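"""Cell-graph construction.

Builds the undirected graph G(v, e) over nucleus centroids as a Delaunay
triangular mesh, then removes outlier triangles that are highly obtuse
(very large or very small interior angles), as such slivers arise at the
convex hull of a finite point set and do not represent cell-cell contacts.
Filtering is triangle-level only: vertices are never deleted, so cell
identity is preserved across metrics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay as _SciPyDelaunay
from scipy.spatial import QhullError

logger = logging.getLogger(__name__)


def cross2d(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """z-component of the cross product of 2-D vectors (broadcasting)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]


@dataclass(frozen=True)
class AngleFilterConfig:
    """Thresholds for the obtuse-triangle outlier rule (radians, strict)."""

    theta_max: float = 5 * math.pi / 6  # 150 degrees
    theta_min: float = math.pi / 12  # 15 degrees

    def __post_init__(self) -> None:
        if not (0 < self.theta_min < math.pi / 3 < self.theta_max < math.pi):
            raise ValueError(
                "require 0 < theta_min < pi/3 < theta_max < pi "
                f"(got theta_min={self.theta_min}, theta_max={self.theta_max})"
            )


@dataclass
class TriangleMesh:
    """Triangular mesh over cell centres: the graph G(v, e).

    ``vertices`` is an (n, 2) float array of (x, y) points, ``triangles`` an
    (m, 3) int array of vertex index triplets. ``edges`` is derived: the set
    of unique unordered index pairs appearing as triangle sides.
    """

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        self.triangles = np.asarray(self.triangles, dtype=int).reshape(-1, 3)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle index out of range")

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as a sorted (k, 2) index array."""
        if not len(self.triangles):
            return np.empty((0, 2), dtype=int)
        sides = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        sides.sort(axis=1)
        return np.unique(sides, axis=0)

    def triangle_coords(self) -> np.ndarray:
        """(m, 3, 2) array of vertex coordinates per triangle."""
        return self.vertices[self.triangles]


def _triangle_angles(coords: np.ndarray) -> np.ndarray:
    """Interior angles (m, 3) of triangles given as (m, 3, 2) coordinates."""
    out = np.empty(coords.shape[:2])
    for i in range(3):
        a = coords[:, (i + 1) % 3] - coords[:, i]
        b = coords[:, (i + 2) % 3] - coords[:, i]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        cosv = np.einsum("ij,ij->i", a, b) / (na * nb)
        out[:, i] = np.arccos(np.clip(cosv, -1.0, 1.0))
    return out


def delaunay(points: np.ndarray | list, dedup_tol: float = 1e-9) -> TriangleMesh:
    """Delaunay-triangulate a 2-D point set.

    Duplicate points (within ``dedup_tol``) are merged with a warning. Points
    are ordered lexicographically before triangulation so cocircular ties are
    resolved deterministically. Degenerate (zero-area) simplices are dropped.
    Raises ``ValueError`` for fewer than 3 usable points or a collinear set.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts):
        # snap-to-grid dedup, then lexicographic order for determinism
        snapped = np.round(pts / max(dedup_tol, 1e-300)) * dedup_tol
        _, keep_idx = np.unique(snapped, axis=0, return_index=True)
        if len(keep_idx) < len(pts):
            logger.warning("merged %d duplicate point(s)", len(pts) - len(keep_idx))
        pts = pts[np.sort(keep_idx)]
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        pts = pts[order]
    if len(pts) < 3:
        raise ValueError("need at least 3 distinct points to triangulate")
    try:
        tri = _SciPyDelaunay(pts)
    except QhullError as exc:
        raise ValueError(f"degenerate point set (collinear?): {exc}") from exc
    simplices = tri.simplices
    if simplices.size == 0:
        raise ValueError("all points collinear: no triangulation exists")
    coords = pts[simplices]
    area2 = np.abs(cross2d(coords[:, 1] - coords[:, 0], coords[:, 2] - coords[:, 0]))
    simplices = simplices[area2 > 0]
    # canonical triangle representation: sorted indices, sorted rows
    simplices = np.sort(simplices, axis=1)
    simplices = simplices[np.lexsort(simplices.T[::-1])]
    return TriangleMesh(vertices=pts, triangles=simplices)


def filter_obtuse(
    mesh: TriangleMesh, config: AngleFilterConfig | None = None
) -> TriangleMesh:
    """Drop triangles whose max angle > theta_max or min angle < theta_min.

    Inequalities are strict, so a triangle at exactly a threshold is retained.
    Vertices are unchanged; edges are implicitly recomputed from survivors.
    """
    config = config or AngleFilterConfig()
    if not mesh.n_triangles:
        return TriangleMesh(mesh.vertices.copy(), mesh.triangles.copy())
    ang = _triangle_angles(mesh.triangle_coords())
    keep = (ang.max(axis=1) <= config.theta_max) & (ang.min(axis=1) >= config.theta_min)
    return TriangleMesh(mesh.vertices.copy(), mesh.triangles[keep])


def build_graph(mesh: TriangleMesh) -> nx.Graph:
    """Undirected adjacency graph over the unique mesh edges.

    Every vertex is a node (with ``x``/``y`` attributes) even if all its
    incident triangles were filtered, in which case it has degree 0.
    """
    g = nx.Graph()
    for i, (x, y) in enumerate(mesh.vertices):
        g.add_node(int(i), x=float(x), y=float(y))
    for i, j in mesh.edges:
        d = float(np.linalg.norm(mesh.vertices[j] - mesh.vertices[i]))
        g.add_edge(int(i), int(j), length=d)
    return g


def to_graphml(mesh: TriangleMesh, path) -> None:
    nx.write_graphml(build_graph(mesh), path)


def triangles_to_frame(mesh: TriangleMesh):
    import pandas as pd

    return pd.DataFrame(
        {
            "triangle_id": np.arange(mesh.n_triangles),
            "idxA": mesh.triangles[:, 0] if mesh.n_triangles else [],
            "idxB": mesh.triangles[:, 1] if mesh.n_triangles else [],
            "idxC": mesh.triangles[:, 2] if mesh.n_triangles else [],
        }
    )
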