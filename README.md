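# epimesh

Graph-based quantification of epithelial topology from nuclei-stained
fluorescence microscopy images.

Loss of cell-cell adhesion — for instance through dysfunctional E-cadherin,
as in the cancer-associated mutants A634V, R749W and P799R — disturbs how
cells distribute in an epithelial monolayer. `epimesh` measures that
disturbance without segmenting cytoplasms or membranes: it segments the
DAPI-stained nuclei, connects their geometric centres υ_k into an undirected
graph G(υ, ε) via Delaunay triangulation, and scores the regularity of the
resulting triangular mesh. It is intended for cell biologists and image
analysts comparing spatial organisation between experimental conditions.

## The metrics

Each mesh triangle k has vertices (v_A, v_B, v_C), edge lengths
d = (d_AB, d_BC, d_CA) with d_ij = ‖v_j − v_i‖, interior angles (α, β, γ)
and area A_k = ½|ε₁ × ε₂|. Four quantities characterise a network:

- **edge length** d_ij — the internuclear distance of each unique edge;
- **triangle area** A_k;
- **length distortion** γ_k = Var(d_AB, d_BC, d_CA) / d̄² — the variance of
  the three edge lengths over the squared mean edge length; dimensionless,
  scale-invariant, zero iff the triangle is equilateral;
- **angle distortion** φ_k = ⅓ Σ (θ − π/3)² — the variance of the interior
  angles about the equilateral angle, in rad²; zero iff equilateral.

Highly obtuse Delaunay slivers (max angle > 150° or min angle < 15°, both
configurable) are removed before analysis. Conditions are compared per
metric with two-sided Mann-Whitney U tests (exact for small untied samples,
tie- and continuity-corrected normal approximation otherwise), with stars at
p ≤ 0.05 / 0.01 / 0.001 / 0.0001.

A synthetic benchmark distorts a regular 56-point triangular lattice by
moving every node p_k to p_k + β·η with η ~ N(0, I): β = 0 is a homogeneous
network, β = 100 a highly heterogeneous one. All four metrics increase with
β, which is how the package validates its own sensitivity.

## Worked example

Simulate a homogeneous (β = 0) and a distorted (β = 60) condition, render
each as a synthetic nuclei image, then run the full image → graph → metrics
→ statistics pipeline:

```sh
epimesh simulate --betas 0  --replicates 1 --n-points 56 --extent 800 --seed 7 -o wt  --render
epimesh simulate --betas 60 --replicates 1 --n-points 56 --extent 800 --seed 7 -o mut --render
epimesh segment wt/beta0.tif  -o wt
epimesh segment mut/beta60.tif -o mut
epimesh analyze wt/beta0_centroids.csv   -o wt
epimesh analyze mut/beta60_centroids.csv -o mut
epimesh compare wt/beta0_summary.json mut/beta60_summary.json -o comparisons.csv
```

which prints:

```
wt/beta0.tif: 56 nuclei -> wt/beta0_centroids.csv
mut/beta60.tif: 52 nuclei -> mut/beta60_centroids.csv
beta0: 90 triangles, 145 edges; mean area 5656.51 px^2, mean edge 117.75 px, mean gamma 0.0051, mean phi 0.0364 rad^2
beta60: 71 triangles, 130 edges; mean area 6409.57 px^2, mean edge 131.14 px, mean gamma 0.0578, mean phi 0.2303 rad^2
area: beta0 vs beta60 (n=90/71) U=2790.0 p=0.1684 ns
edge_length: beta0 vs beta60 (n=145/130) U=7090.0 p=0.0003916 ***
gamma: beta0 vs beta60 (n=90/71) U=294.0 p=5.301e-23 ****
phi: beta0 vs beta60 (n=90/71) U=372.0 p=7.24e-22 ****
```

The distorted condition recovers fewer nuclei (some rendered disks merge
after perturbation), and its mesh shows markedly higher length and angle
distortion — the distortions separate the two conditions far more sharply
than raw area does. Units are pixels here; pass `--pixel-size-um` to report
μm/μm². Every output embeds the tool version, resolved configuration and
seed, and reruns are byte-identical for a fixed seed.

The same functionality is available as a library:

```python
from epimesh import DistortionConfig, make_network, summarize_mesh

mesh = make_network(DistortionConfig(beta=20.0, seed=1))
print(summarize_mesh(mesh).means)
```

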