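# Methods

## Overview

`epimesh` turns a 2-D fluorescence image of DAPI-stained nuclei into an
undirected cell graph and quantifies the regularity of the tissue's spatial
organisation. The pipeline has four stages: (1) nuclei segmentation,
(2) Delaunay mesh construction over the nucleus centroids, (3) per-triangle
geometry and regularity metrics, (4) nonparametric comparison between
conditions. A synthetic module generates distorted benchmark networks and
rendered ground-truth images.

The central assumption is that nucleus positions are an adequate proxy for
cell positions, so cell-cell neighbourhood structure can be read off the
Delaunay triangulation of the nucleus centres without segmenting cytoplasms
or membranes. This holds for contact-inhibited monolayers imaged roughly
perpendicular to the substrate; it degrades for multilayered or highly
elongated cells, where nucleus position and cell contact topology decouple.

## Segmentation pipeline

Stages, in order, with defaults:

| stage | operation | parameters (default) |
|---|---|---|
| channel | extract DAPI channel, max-normalise to [0, 1] | `channel="blue"` |
| denoise | pluggable: none / median / gaussian / total-variation | `tv`, weight 0.1 |
| sharpen | unsharp mask `I + a (I − G_r I)`, clipped to [0, 1] | amount 1.0, radius 2 px |
| stretch | `(I − low)/(high − low)` clipped to [0, 1] | low 0.1, high 0.5 |
| threshold | Otsu over a 256-bin histogram; foreground = `I > t` | — |
| cleanup | drop white components < `min_size` px (8-conn); fill black holes < `min_size` px (4-conn) | `min_size=60` |
| contours | Moore-Neighbor tracing, Jacob's stopping criterion | — |
| fill + centroid | raster-fill each closed contour; centroid = mean of foreground pixel coordinates | — |

Notes on the individual stages:

- The denoiser is pluggable because the appropriate noise model depends on
  the detector; the total-variation default (Chambolle) favours piecewise
  constant solutions, which suits the quasi-binary target of the stretch
  step. For photon-limited images a variance-stabilising transform before
  TV would be better; this is out of scope.
- The saturation stretch maps intensities at or below `low` to 0 and at or
  above `high` to 1, expanding the transition band linearly. The boundary
  convention (0.1 → 0, 0.5 → 1) is the continuous limit of the strict
  inequalities and is configurable.
- The size rule is strict: a 59-pixel component is removed, a 60-pixel one
  kept. Foreground components use 8-connectivity and holes 4-connectivity,
  the standard complementary pairing that avoids topological paradoxes.
  (scikit-image ≥ 0.26 `max_size` semantics are ≤-inclusive, so the
  implementation passes `min_size − 1`.)
- Contour tracing walks the 8-neighbourhood clockwise from the
  uppermost-leftmost pixel of each component and terminates when the start
  pixel is re-entered from its original (western) entry direction. An
  isolated pixel yields a length-1 contour. Components touching the image
  border are traced within bounds and flagged; they are retained by default
  and can be dropped downstream (`analyze --drop-border`).
- Coordinates are 0-based `(row, col)`; centroids are reported as
  `(x=col, y=row)` in pixels and scaled by `pixel_size_um` for physical
  units.
- Interactive correction of mis-segmented nuclei is replaced by an optional
  override CSV (`action ∈ {add, remove}, x, y`) applied after segmentation;
  `remove` drops the nearest centroid within 5 px.

## Mesh construction

Centroids are deduplicated (tolerance 1e-9 px, with a warning — microscopy
rounding can duplicate centroids), ordered lexicographically so cocircular
ties are resolved deterministically, and triangulated (Qhull via scipy).
Among all triangulations of a point set the Delaunay triangulation
maximises the minimum interior angle, which is why it is the canonical
choice for neighbourhood graphs. Degenerate zero-area simplices are
dropped; fewer than three usable points or a collinear set is an error.

Sliver triangles along the convex hull do not represent cell contacts, so
triangles with max angle > θ_max or min angle < θ_min are removed
(defaults 5π/6 and π/12; strict inequalities, so a triangle exactly at a
threshold survives). The exact thresholds are a package decision — the
intent is only to drop angles far above/below π/2 — and the test suite's
properties do not depend on their precise values. Filtering is
triangle-level: vertices are never deleted, so a cell whose every incident
triangle is removed remains in the graph with degree 0 and cell identity is
stable across metrics.

## Metrics

For triangle k with edge lengths d = (d_AB, d_BC, d_CA), angles (α, β, γ)
and mean edge d̄:

- γ_k = Var(d)/d̄², φ_k = Var over the angles of (θ − π/3)².
- The variance over the three items is the population variance (divide
  by 3); the three edges of one triangle are a complete population, not a
  sample. A `ddof=1` option exists for sensitivity checks.
- φ deviations are taken from π/3; since α + β + γ = π this equals the
  variance about the triangle's own mean angle.
- Both distortions are invariant under translation, rotation, reflection
  and uniform scaling, and vanish exactly iff the triangle is equilateral.
- Edge-length observations are pooled over the **unique** edge set, so a
  shared internuclear distance is counted once; per-triangle pooling
  (3 sides per triangle) is available via `edge_pooling="per_triangle"`.

Areas are ½|ε₁ × ε₂| (cross product of two edge vectors); lengths scale by
`pixel_size_um` and areas by its square.

## Synthetic distortion model

The generator places `n_points` (default 56) on a triangular lattice inside
a square plane of `extent` 1000 px (the scale of a typical microscopy
field), staggering alternate rows by half the horizontal spacing so the
β = 0 Delaunay mesh tiles the interior with congruent equilateral
triangles; 56 points form 8 staggered rows of 7. Each node is displaced by
β·η with η ~ N(0, I) i.i.d. per node, without redrawing or clipping points
that leave the plane. β is in pixel units (η has unit variance per axis).
A square-lattice layout is available for comparison. If `n_points` does not
tile the nearest rows × cols grid, the nearest feasible grid is used with a
warning.

Zero-distortion assertions are restricted to interior triangles — those not
touching a convex-hull vertex or any of its graph neighbours — because a
finite lattice's boundary contains 120° half-rhombus slivers whose vertices
are not hull vertices.

The distortion sweep (β ∈ {0, 5, 10, 20, 50, 100}, 50 replicates) uses a
common-random-numbers design: each replicate draws one unit displacement
field η (independent across replicates) and scales it by every β in turn.
This pairs the β levels within replicates, matches the model's defining
scaling property (β·η with shared η), and estimates the dose-response with
far less Monte-Carlo noise than independent draws per (β, replicate).
Mean edge length, γ and φ respond monotonically across the whole range;
mean triangle area is flat to first order below β ≈ 10 — displacement
redistributes area within a nearly fixed convex hull, and the obtuse filter
removes the expansion slivers — and rises clearly from β ≈ 20 upward.

The image renderer draws hard disks (radius 10 px, intensity 0.9 over
background 0.05) at given points with seeded Poisson noise
(`noise_level` = relative standard deviation at unit intensity, default
0.05). It emulates well-separated, uniformly stained nuclei only: no
texture, shape variation, PSF blur or intensity gradients. Passing the
recovery tests therefore demonstrates the pipeline's geometric correctness,
not robustness to real staining variability; disks that overlap after
perturbation merge into one segmented object, which mirrors what dense real
images do to any intensity-threshold segmenter.

## Statistics

Two-sided Mann-Whitney U; exact null enumeration when n₁ + n₂ ≤ 16 with no
ties, otherwise the normal approximation with tie and continuity
corrections (the method used is recorded in every result row). Sampling
units are triangles (area, γ, φ) and unique edges (length), pooled across
replicate images per condition — a deliberate simplification that ignores
image-level clustering. Raw p-values are reported with stars at
0.05/0.01/0.001/0.0001; Benjamini-Hochberg adjustment is available but off
by default, and never affects the stars.

## Numerical choices and degenerate inputs

- Otsu on a constant image raises rather than silently returning an empty
  mask; a blank image yields an empty nucleus set with a warning.
- Arc-cosine arguments are clipped to [−1, 1]; angle sums are validated to
  π within 1e-6 before φ is computed.
- Collinear triples have area 0 and are excluded from meshes at
  construction.
- All simulation randomness flows through `numpy` `SeedSequence` spawning,
  so per-replicate streams are independent and the whole pipeline is
  reproducible — outputs embed version, config and seed, contain no
  timestamps, and rerun byte-identically.

## Problem sizes

Default test and acceptance workloads are desk-scale: 56-point networks
(the study condition), 6 × 50 sweep networks, twenty 256 × 256 rendered
images with 8 nuclei each, and 2000 null simulations at n = 20 per group.
These sizes give tight Monte-Carlo behaviour for every property checked
while keeping the full suite under a minute of compute.

## Known limitations

- 2-D only; no 3-D stacks, time-lapse tracking, or cytoplasm segmentation.
- The segmentation front-end assumes roughly convex, non-touching nuclei;
  touching nuclei merge (no watershed splitting).
- The obtuse-filter thresholds are heuristics; extremely distorted networks
  can lose many (rarely all) triangles, which the sweep records as missing.
- Pooling triangles across images treats them as independent observations;
  between-image variance is not modelled.
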