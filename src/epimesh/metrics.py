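"""Per-triangle geometry and network regularity metrics.

Four quantities characterise a cell network: edge (internuclear) length
d_ij, triangle area A_k, length distortion gamma_k and angle distortion
phi_k. Both distortions vanish exactly for an equilateral triangle and
measure departure from it:

    gamma_k = Var(d_AB, d_BC, d_CA) / d_mean^2      (dimensionless)
    phi_k   = Var(alpha, beta, gamma about pi/3)    (radians^2)

The variance over the three items is the population variance by default
(divide by 3); normalising gamma_k by the squared mean edge length makes it
invariant to triangle size. phi_k deviations are taken from pi/3, which is
numerically identical to the variance about the triangle's own mean angle
since the three interior angles always sum to pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meshing import TriangleMesh, cross2d


def edge_lengths(vA, vB, vC) -> tuple[float, float, float]:
    """Euclidean lengths (d_AB, d_BC, d_CA) of the triangle sides."""
    vA, vB, vC = (np.asarray(v, dtype=float) for v in (vA, vB, vC))
    d = (
        float(np.linalg.norm(vB - vA)),
        float(np.linalg.norm(vC - vB)),
        float(np.linalg.norm(vA - vC)),
    )
    if min(d) == 0.0:
        raise ValueError("coincident vertices: zero-length edge")
    return d


def angles(vA, vB, vC) -> tuple[float, float, float]:
    """Interior angles (alpha, beta, gamma) at vA, vB, vC in radians.

    Each angle is the arc-cosine of the normalized dot product of the two
    edge vectors incident at that vertex; the three sum to pi.
    """
    vA, vB, vC = (np.asarray(v, dtype=float) for v in (vA, vB, vC))
    out = []
    for p, q, r in ((vA, vB, vC), (vB, vC, vA), (vC, vA, vB)):
        e1, e2 = q - p, r - p
        n1, n2 = np.linalg.norm(e1), np.linalg.norm(e2)
        if n1 == 0 or n2 == 0:
            raise ValueError("zero-length edge: angle undefined")
        out.append(float(np.arccos(np.clip(np.dot(e1, e2) / (n1 * n2), -1.0, 1.0))))
    return tuple(out)


def triangle_area(vA, vB, vC) -> float:
    """Area A = |e1 x e2| / 2, the half-magnitude of the edge cross product.

    Collinear vertices give area 0 (degenerate, flagged by callers).
    """
    vA, vB, vC = (np.asarray(v, dtype=float) for v in (vA, vB, vC))
    return float(abs(cross2d(vB - vA, vC - vA))) / 2.0


def length_distortion(d_AB: float, d_BC: float, d_CA: float, ddof: int = 0) -> float:
    """gamma_k: variance of the three edge lengths over the squared mean.

    Zero iff the triangle is equilateral; invariant to uniform scaling.
    ``ddof=0`` (population variance over the three fixed items) is the
    default; ``ddof=1`` gives the sample-variance convention.
    """
    d = np.array([d_AB, d_BC, d_CA], dtype=float)
    if np.any(d <= 0):
        raise ValueError("edge lengths must be positive")
    return float(np.var(d, ddof=ddof) / d.mean() ** 2)


def angle_distortion(
    alpha: float, beta: float, gamma: float, ddof: int = 0, tol: float = 1e-6
) -> float:
    """phi_k: mean squared deviation of the angles from pi/3, in radians^2."""
    a = np.array([alpha, beta, gamma], dtype=float)
    if abs(a.sum() - np.pi) > tol:
        raise ValueError(f"angles sum to {a.sum():.6f}, expected pi")
    dev = a - np.pi / 3
    n = 3 - ddof
    return float(np.sum(dev**2) / n)


def triangle_records(mesh: TriangleMesh, pixel_size: float = 1.0, ddof: int = 0) -> pd.DataFrame:
    """One row of geometry per triangle: edges, angles, area, distortions.

    Lengths are multiplied by ``pixel_size`` (areas by its square) so records
    are in physical units when a calibration is supplied.
    """
    rows = []
    coords = mesh.triangle_coords() * pixel_size
    for k, (vA, vB, vC) in enumerate(coords):
        d = edge_lengths(vA, vB, vC)
        ang = angles(vA, vB, vC)
        rows.append(
            {
                "triangle_id": k,
                "d_AB": d[0],
                "d_BC": d[1],
                "d_CA": d[2],
                "alpha": ang[0],
                "beta": ang[1],
                "gamma_angle": ang[2],
                "mean_edge": float(np.mean(d)),
                "area": triangle_area(vA, vB, vC),
                "gamma_k": length_distortion(*d, ddof=ddof),
                "phi_k": angle_distortion(*ang, ddof=ddof),
            }
        )
    cols = [
        "triangle_id", "d_AB", "d_BC", "d_CA", "alpha", "beta", "gamma_angle",
        "mean_edge", "area", "gamma_k", "phi_k",
    ]
    return pd.DataFrame(rows, columns=cols)


def edge_records(mesh: TriangleMesh, pixel_size: float = 1.0) -> pd.DataFrame:
    """One row per unique undirected edge: endpoint indices and length."""
    e = mesh.edges
    if len(e):
        lengths = np.linalg.norm(
            mesh.vertices[e[:, 1]] - mesh.vertices[e[:, 0]], axis=1
        ) * pixel_size
    else:
        lengths = np.empty(0)
    return pd.DataFrame({"i": e[:, 0] if len(e) else [], "j": e[:, 1] if len(e) else [],
                         "length": lengths})


@dataclass
class MeshSummary:
    """Per-mesh metric distributions and their means / standard errors.

    Edge-length observations are taken over the unique edge set by default
    (each internuclear distance counted once); ``edge_pooling='per_triangle'``
    instead counts each triangle's three sides, double-weighting shared edges.
    """

    areas: np.ndarray
    edge_lengths: np.ndarray
    gammas: np.ndarray
    phis: np.ndarray
    n_triangles: int
    n_edges: int
    n_vertices: int
    units: str = "px"

    _METRICS = ("area", "edge_length", "gamma", "phi")

    def values(self, metric: str) -> np.ndarray:
        try:
            return {
                "area": self.areas,
                "edge_length": self.edge_lengths,
                "gamma": self.gammas,
                "phi": self.phis,
            }[metric]
        except KeyError:
            raise KeyError(f"unknown metric {metric!r}; expected one of {self._METRICS}") from None

    @property
    def means(self) -> dict[str, float]:
        return {m: float(np.mean(self.values(m))) for m in self._METRICS}

    @property
    def ses(self) -> dict[str, float]:
        out = {}
        for m in self._METRICS:
            v = self.values(m)
            out[m] = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
        return out

    def to_dict(self) -> dict:
        return {
            "units": self.units,
            "n_triangles": self.n_triangles,
            "n_edges": self.n_edges,
            "n_vertices": self.n_vertices,
            "means": self.means,
            "ses": self.ses,
            "observations": {m: self.values(m).tolist() for m in self._METRICS},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MeshSummary":
        obs = d["observations"]
        return cls(
            areas=np.asarray(obs["area"], dtype=float),
            edge_lengths=np.asarray(obs["edge_length"], dtype=float),
            gammas=np.asarray(obs["gamma"], dtype=float),
            phis=np.asarray(obs["phi"], dtype=float),
            n_triangles=d["n_triangles"],
            n_edges=d["n_edges"],
            n_vertices=d["n_vertices"],
            units=d["units"],
        )


def summarize_mesh(
    mesh: TriangleMesh,
    pixel_size: float = 1.0,
    edge_pooling: str = "unique",
    ddof: int = 0,
) -> MeshSummary:
    """Aggregate per-triangle records into per-mesh metric distributions."""
    if not mesh.n_triangles:
        raise ValueError("empty mesh: no triangles to summarize")
    rec = triangle_records(mesh, pixel_size=pixel_size, ddof=ddof)
    if edge_pooling == "unique":
        lengths = edge_records(mesh, pixel_size=pixel_size)["length"].to_numpy()
    elif edge_pooling == "per_triangle":
        lengths = rec[["d_AB", "d_BC", "d_CA"]].to_numpy().ravel()
    else:
        raise ValueError(f"unknown edge_pooling {edge_pooling!r}")
    return MeshSummary(
        areas=rec["area"].to_numpy(),
        edge_lengths=lengths,
        gammas=rec["gamma_k"].to_numpy(),
        phis=rec["phi_k"].to_numpy(),
        n_triangles=mesh.n_triangles,
        n_edges=len(mesh.edges),
        n_vertices=len(mesh.vertices),
        units="um" if pixel_size != 1.0 else "px",
    )
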