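"""Synthetic distorted networks and rendered nuclei fixtures.

The distortion model starts from a regular planar layout of ``n_points``
nodes (default 56, on a triangular lattice so the undistorted Delaunay mesh
tiles the plane with congruent near-equilateral triangles) and displaces
every node p_k to p_k + beta * eta, with eta drawn i.i.d. from the standard
bivariate normal (zero mean, identity covariance). beta = 0 is the
homogeneous reference network; larger beta gives progressively more
heterogeneous, disorganized node patterns. Displaced points may leave the
plane extent; they remain valid mesh nodes.

A companion renderer draws bright nucleus-like disks at given points over a
dark background with optional seeded Poisson noise, returning the image
together with ground-truth centroids, so the segmentation front-end can be
benchmarked against known answers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meshing import AngleFilterConfig, TriangleMesh, delaunay, filter_obtuse
from .metrics import MeshSummary, summarize_mesh

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistortionConfig:
    """Parameters of the synthetic distortion model."""

    n_points: int = 56
    extent: float = 1000.0
    beta: float = 0.0
    seed: int | None = None
    layout: str = "triangular_lattice"

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("need at least 3 points")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.extent <= 0:
            raise ValueError("extent must be positive")


@dataclass(frozen=True)
class SyntheticImageConfig:
    """Parameters of the nucleus-disk renderer."""

    shape: tuple[int, int] = (256, 256)
    nucleus_radius: float = 10.0
    intensity: float = 0.9
    background: float = 0.05
    noise_level: float = 0.05  # relative Poisson std at unit intensity; 0 = noiseless
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.nucleus_radius < 1:
            raise ValueError("nucleus radius must be >= 1 px")
        if not (0 < self.intensity <= 1):
            raise ValueError("intensity must be in (0, 1]")


def _grid_dims(n_points: int) -> tuple[int, int]:
    """Rows x cols closest to square with rows*cols >= n_points, rows >= cols."""
    rows = math.ceil(math.sqrt(n_points))
    cols = math.ceil(n_points / rows)
    return rows, cols


def generate_base_lattice(config: DistortionConfig) -> np.ndarray:
    """Deterministic regular layout of ``n_points`` within the extent.

    ``triangular_lattice`` staggers alternate rows by half the horizontal
    spacing so interior Delaunay triangles are equilateral; 56 points give 8
    staggered rows of 7. ``square_lattice`` is an axis-aligned grid. If no
    rows x cols factorization matches ``n_points`` exactly the nearest
    feasible grid is used with a warning.
    """
    rows, cols = _grid_dims(config.n_points)
    if rows * cols != config.n_points:
        logger.warning(
            "%d points do not tile a %dx%d grid; generating %d points",
            config.n_points, rows, cols, rows * cols,
        )
    a = config.extent / cols  # horizontal spacing
    if config.layout == "triangular_lattice":
        dy = a * math.sqrt(3) / 2
        pts = []
        for r in range(rows):
            x0 = a / 2 if r % 2 else 0.0
            for c in range(cols):
                pts.append((x0 + c * a, r * dy))
        pts = np.array(pts, dtype=float)
    elif config.layout == "square_lattice":
        xs = np.arange(cols) * a
        ys = np.arange(rows) * a
        pts = np.array([(x, y) for y in ys for x in xs], dtype=float)
    else:
        raise ValueError(f"unknown layout {config.layout!r}")
    # centre the lattice in the extent
    span = pts.max(axis=0) - pts.min(axis=0)
    pts += (np.array([config.extent, config.extent]) - span) / 2 - pts.min(axis=0)
    return pts


def perturb_points(
    points: np.ndarray, beta: float, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Displace each point by beta * eta, eta ~ N(0, I) bivariate.

    beta = 0 returns the coordinates unchanged; no clipping to the extent.
    For a fixed seed, doubling beta exactly doubles every displacement.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    points = np.asarray(points, dtype=float)
    if beta == 0:
        return points.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return points + beta * rng.standard_normal(points.shape)


def hull_vertex_indices(mesh: TriangleMesh) -> np.ndarray:
    """Indices of mesh vertices on the convex hull boundary."""
    from scipy.spatial import ConvexHull

    return np.unique(ConvexHull(mesh.vertices).vertices)


def interior_triangle_mask(mesh: TriangleMesh) -> np.ndarray:
    """Boolean mask of triangles away from the mesh boundary.

    Excluded are triangles touching a convex-hull vertex or any of its graph
    neighbours. Boundary triangles of a finite lattice need not be
    equilateral even at beta = 0 (the staggered rows leave 120-degree
    slivers along the zigzag edge whose vertices are not hull vertices), so
    zero-distortion assertions apply to interior triangles only.
    """
    boundary = set(hull_vertex_indices(mesh).tolist())
    extended = set(boundary)
    for i, j in mesh.edges:
        if i in boundary:
            extended.add(int(j))
        if j in boundary:
            extended.add(int(i))
    return np.array(
        [not (set(t) & extended) for t in mesh.triangles.tolist()], dtype=bool
    )


def make_network(config: DistortionConfig, filter_config: AngleFilterConfig | None = None) -> TriangleMesh:
    """Lattice -> perturb -> Delaunay -> obtuse filter, in one call."""
    pts = generate_base_lattice(config)
    pts = perturb_points(pts, config.beta, config.seed)
    mesh = delaunay(pts)
    return filter_obtuse(mesh, filter_config)


def distortion_sweep(
    betas=(0.0, 5.0, 10.0, 20.0, 50.0, 100.0),
    replicates: int = 50,
    n_points: int = 56,
    extent: float = 1000.0,
    layout: str = "triangular_lattice",
    seed: int | None = None,
    filter_config: AngleFilterConfig | None = None,
) -> pd.DataFrame:
    """Metric response to the distortion level beta.

    Each replicate draws one unit displacement field eta (independent across
    replicates) and scales it by every beta in turn - a common-random-numbers
    design, so differences between beta levels are paired within replicates
    and the dose-response is estimated with far less Monte-Carlo noise than
    independent draws per (beta, replicate). Each network is triangulated,
    obtuse-filtered and summarized; a mesh whose triangles are all filtered
    away is recorded with NaN metrics rather than aborting the sweep.
    """
    betas = list(betas)
    if any(b < 0 for b in betas):
        raise ValueError("betas must be non-negative")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    base = generate_base_lattice(
        DistortionConfig(n_points=n_points, extent=extent, layout=layout)
    )
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(replicates)):
        eta = np.random.default_rng(child).standard_normal(base.shape)
        for beta in betas:
            pts = base + beta * eta
            mesh = filter_obtuse(delaunay(pts), filter_config)
            row = {"beta": beta, "replicate": rep, "n_triangles": mesh.n_triangles}
            if mesh.n_triangles:
                s = summarize_mesh(mesh)
                row.update(
                    mean_area=s.means["area"],
                    mean_edge=s.means["edge_length"],
                    mean_gamma=s.means["gamma"],
                    mean_phi=s.means["phi"],
                )
            else:
                row.update(mean_area=np.nan, mean_edge=np.nan,
                           mean_gamma=np.nan, mean_phi=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def sweep_summary(sweep: pd.DataFrame) -> pd.DataFrame:
    """Mean and dispersion of each metric per beta level."""
    agg = sweep.groupby("beta")[["mean_area", "mean_edge", "mean_gamma", "mean_phi"]]
    out = agg.agg(["mean", "std"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()


def pooled_summary(config: DistortionConfig, replicates: int, seed: int | None = None,
                   filter_config: AngleFilterConfig | None = None) -> MeshSummary:
    """Pool per-triangle/per-edge observations over replicate networks."""
    ss = np.random.SeedSequence(seed)
    areas, lengths, gammas, phis = [], [], [], []
    n_tri = n_edge = n_vert = 0
    for child in ss.spawn(replicates):
        rng = np.random.default_rng(child)
        pts = perturb_points(generate_base_lattice(config), config.beta, rng)
        mesh = filter_obtuse(delaunay(pts), filter_config)
        if not mesh.n_triangles:
            continue
        s = summarize_mesh(mesh)
        areas.append(s.areas)
        lengths.append(s.edge_lengths)
        gammas.append(s.gammas)
        phis.append(s.phis)
        n_tri += s.n_triangles
        n_edge += s.n_edges
        n_vert += s.n_vertices
    if not areas:
        raise ValueError("every replicate mesh degenerated")
    return MeshSummary(
        areas=np.concatenate(areas),
        edge_lengths=np.concatenate(lengths),
        gammas=np.concatenate(gammas),
        phis=np.concatenate(phis),
        n_triangles=n_tri,
        n_edges=n_edge,
        n_vertices=n_vert,
    )


def render_nuclei_image(
    points: np.ndarray, config: SyntheticImageConfig
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render bright disks at ``points`` and return (image, ground truth).

    Ground truth holds the requested (x, y) centres and the centroid of each
    rasterized disk. Overlapping disks (centre distance < 2 r) are flagged in
    an ``overlap`` column, voiding the centroid guarantee for those nuclei.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    h, w = config.shape
    img = np.full((h, w), config.background, dtype=float)
    rr, cc = np.mgrid[0:h, 0:w]
    raster_centroids = []
    for x, y in points:
        disk = (rr - y) ** 2 + (cc - x) ** 2 <= config.nucleus_radius**2
        img[disk] = config.intensity
        if disk.any():
            raster_centroids.append((cc[disk].mean(), rr[disk].mean()))
        else:
            raster_centroids.append((np.nan, np.nan))
    overlap = np.zeros(len(points), dtype=bool)
    if len(points) > 1:
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(points))
        np.fill_diagonal(d, np.inf)
        overlap = d.min(axis=1) < 2 * config.nucleus_radius
        if overlap.any():
            logger.warning("%d overlapping disk(s): centroid guarantee void", overlap.sum())
    if config.noise_level > 0:
        rng = np.random.default_rng(config.seed)
        lam = 1.0 / config.noise_level**2  # expected photon count at unit intensity
        img = rng.poisson(img * lam) / lam
        img = np.clip(img, 0.0, 1.0)
    truth = pd.DataFrame(
        {
            "nucleus_id": np.arange(len(points)),
            "x_true": points[:, 0],
            "y_true": points[:, 1],
            "x_raster": [c[0] for c in raster_centroids],
            "y_raster": [c[1] for c in raster_centroids],
            "overlap": overlap,
        }
    )
    return img, truth


def random_disk_layout(
    n: int,
    shape: tuple[int, int],
    radius: float,
    rng: np.random.Generator,
    margin: float = 2.0,
    max_tries: int = 10000,
) -> np.ndarray:
    """Rejection-sample ``n`` non-overlapping disk centres within ``shape``.

    Centres keep ``2*radius + margin`` from each other and ``radius + margin``
    from the border. Raises if the layout cannot be placed.
    """
    h, w = shape
    lo = radius + margin
    pts: list[tuple[float, float]] = []
    for _ in range(max_tries):
        if len(pts) == n:
            break
        x = rng.uniform(lo, w - lo)
        y = rng.uniform(lo, h - lo)
        if all((x - px) ** 2 + (y - py) ** 2 >= (2 * radius + margin) ** 2 for px, py in pts):
            pts.append((x, y))
    if len(pts) < n:
        raise RuntimeError(f"could not place {n} non-overlapping disks")
    return np.array(pts, dtype=float)
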