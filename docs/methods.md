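# Methods

## Geometry substrate

Every analysis consumes a `NeuronGeometry`: a rooted acyclic tree of 3D
nodes in µm with optional per-node radii.  The root is the soma.
Segments are derived, not stored: maximal unbranched chains whose interior
nodes have exactly one child, enumerated deterministically by depth-first
traversal with children sorted by node id.  Axons are tagged at the
segment level and must terminate at leaves; "terminating tips" are leaves
that are neither the soma nor axonal.  Duplicate consecutive nodes
(zero-length edges, a tracer artifact) are merged at construction with a
logged warning.

SWC type 1 marks the soma and type 2 the axon; a non-positive radius is
read as "not recorded" and written back as −1.  Coordinates are emitted
with shortest-round-trip (`repr`) precision so parse∘write is exact.  The
hoc reader supports the skeleton subset only — `create`, `pt3dadd(x,y,z,diam)`,
`access`/block sections, and `connect child(0), parent(pos)` — ignoring
other statements; diameters are halved to radii; connect loops are a
structure error.  Units are µm throughout with no inference.  Soma
positions across preparations are compared after translating each
preparation so its neuropil center sits at the origin (pure translation;
the anterior-up orientation is metadata only).

## Morphometric battery

- **Paths and tortuosity.** One record per terminating tip.  Path length
  is the sum of consecutive inter-node distances; tortuosity divides it by
  the straight soma-to-tip distance, is ≥ 1 up to float tolerance, and is
  flagged undefined (and excluded from distributions) when the tip
  coincides with the soma.
- **Furcations and branch orders.** A branch point is a non-soma node with
  ≥ 2 children — primary filaments never make the soma a furcation.  The
  first branch point from the soma has order 0; a branch point's order
  counts the branch points crossed since then along its unique path.
- **Branch angles.** At each branch point the stored distal endpoints of
  the adjacent tracer-defined segments are used directly (no arc-length
  resampling).  The law of cosines at P_mid gives θ_mid; the reported
  angle is 180° − θ_mid so a straight continuation scores 0°.
  Multi-furcations contribute one angle per (parent, daughter) pair;
  daughter–daughter angles are not reported; degenerate zero-side
  triangles are skipped.
- **Symmetry index.** Only at bifurcations.  Each daughter's downstream
  length includes its own edge plus all cable below; S = min/max, with a
  zero-length daughter flagged as S = 0.
- **Rall power.** f(X) = r_parent^X − Σ r_daughter^X is solved over
  X ∈ [10⁻³, 20].  An interior sign change is solved by Brent's method to
  10⁻⁶.  Without one (e.g. parent no thicker than its widest daughter,
  where f < 0 everywhere), |f| can be multimodal, so a 4001-point coarse
  scan brackets the global minimum before bounded refinement; results at
  an interval bound are flagged clamped, and ties on flat objectives
  resolve to the lower bound.  Radii at a branch point are per-segment
  means of node radii.
- **Linearized Sholl.** Unipolar somata sit outside the neuropil, so
  concentric spheres are replaced by somatofugal path distance: for each
  of `n_distances` (default 100; the sampling density is exposed as a
  parameter) linearly spaced distances D up to the maximum path length,
  the crossing count is the number of parent–child node pairs whose
  cumulative interval [d_parent, d_child) straddles D.  The half-open
  convention makes a node exactly on a sampled distance count once.  Axons
  are excluded.  Counts are also reported normalized to the per-neuron
  maximum, distances to the maximum path length.
- **Spatial density.** Gaussian KDE (Scott's rule) over node x–y
  coordinates, evaluated at the nodes and rescaled so the per-neuron
  maximum is exactly 1.
- **Hair-like neurites.** Maximal connected runs of nodes all thinner
  than 1 µm diameter whose cable exceeds 50 µm; requires radii.
- **Diameters by order.** 1° = main-path segments (soma to axon
  departures); 2° = segments departing the main path; 3° = their
  daughters; terminating filaments form their own tip class regardless of
  order; axon segments are excluded.  Each segment contributes its mean
  node diameter; per-class mean, SD, and CV are reported.
- **Summary.** One row per neuron (path/branch-point/subtree counts,
  total wiring excluding axons, tortuosity and path-length mean ± SD,
  per-class diameters when radii exist).  Per-neuron means and pooled
  distributions are both emitted by the pipeline, since the two
  conventions answer different questions.

## Subtrees and the tiling bootstrap

The main path is the union of soma-to-axon segment chains (multi-axon
cells have several chains sharing the trunk).  Each secondary segment
departing the main path that reaches ≥ 1 terminating tip roots one
subtree; a branch leading only to an axon does not qualify.  A subtree's
tip cluster has a center of mass (mean tip coordinates), a cluster radius
(mean distance from the center to each tip), and a neuritic field: the
covariance ellipsoid of the tips, semi-axes = `scale`·√eigenvalues with
`scale` defaulting to 2 (≈95% coverage per 1D Gaussian axis).  The fit
criterion is not canonical, so the scale is a parameter.  Fewer than 4
tips, or a rank-deficient covariance, fall back to a sphere of the
cluster radius.

Field overlap is decided in the x-y projection (bird's-eye view of the
neuropil): 360-point boundary sampling of each projected ellipse plus
mutual center containment, tolerance 10⁻⁶ µm; exact conic intersection is
avoided for robustness.  The headline metric is the number of
intersecting unordered pairs; the per-subtree alternative (subtrees
touching ≥ 1 other field) is also emitted because "number of overlapping
subtrees" is ambiguous between the two.

The bootstrap permutes the pooled tip coordinates across subtrees
*without replacement*, preserving per-subtree tip counts and subtree root
positions, and recomputes the mean cluster radius (and optionally the
overlap count) per iteration.  Iterations default to 2000 and are capped
at the number of distinct assignments (the multinomial coefficient) when
that is smaller.  One-sided p-values use the add-one correction,
p = (1 + #{scrambled ≤ observed}) / (1 + n), so p is never 0 and is exactly
1 in the degenerate all-singleton case.  A single seeded generator drives
each run and the seed is recorded in the output.

## Minimal spanning neurite trees

Synthetic trees span carrier points sampled uniformly in an ellipsoid
fitted to the reference neuron's node cloud (covariance axes, scaled by
the order statistic that puts ≥ 95% of nodes inside; coplanar clouds get
a 1 µm axis floor).  Uniformity comes from exact unit-ball sampling
(Gaussian direction, U^(1/3) radius) pushed through the ellipsoid's
affine map.  The root is the reference's first branch point — soma
position is arbitrary in these cells, so the arbor's entry point is the
meaningful origin.

Growth is greedy: repeatedly attach the unconnected point p minimizing
`‖p−n‖ + bf·(PL(n) + ‖p−n‖)` over tree nodes n, where PL(n) is n's path
length to the root.  Writing the path-length term as the *resulting* root
path of the new point makes both cost terms extensive in the new cable;
this is the single most consequential interpretation choice in the
module.  Attachment happens only at existing nodes (no mid-edge
splitting).  Ties break toward the lowest carrier index; coincident
duplicates are merged with a warning.  The implementation caches each
point's best attachment and updates it as nodes join (Prim-style); a
naive full-scan implementation of the same rule serves as the test
oracle.

The carrier count is tuned at bf = 0 by doubling-then-bisection until the
grown tree's branch-point count is within 20% of the reference's (error
after 30 steps reports the best count found), then frozen across the
sweep bf ∈ {0, 0.1, …, 0.6} with the same carrier set, so differences
across bf reflect the cost trade-off alone.  Comparisons use 50-bin
histograms on the union range, normalized to each dataset's maximum bin;
the divergence is the sum of absolute bin differences, and each tree is
flagged for total wiring within 20% of the reference.  Empirically the
sweep trades cable for path length monotonically — total cable
non-decreasing, mean root path non-increasing in bf — and no single bf
minimizes divergence for every metric at once.

## Synthetic data generator

The generator emulates the statistical structure of the real
reconstructions, not any particular cell: a soma offset 150 µm from the
neuropil; a primary neurite of default 300 µm carrying 1–5 axons (always
≥ 20 µm unbranched, so automatic candidate detection finds them); 6–16
subtrees rooted along the primary; tip clusters either tiling a grid
(default spacing 120 µm, dispersion 25 µm) or placed at random; a
furcation mix of 90% bifurcations, 8% trifurcations, 2% higher; target
soma-to-tip path lengths uniform in 200–800 µm; and optional radii
tapering 18 → 7 → 3.5 → 1.5 µm across the 1°/2°/3°/tip classes with
multiplicative log-normal noise (σ configurable; the defaults keep σ = 0
so class means are recovered exactly, and σ ≈ 0.3–1 reproduces the high
within-class CVs seen in real cells).

Growth uses direction inheritance: each branch continues its parent's
direction, perturbed per step by `tortuosity_factor`-scaled Gaussian
jitter plus attraction toward the subtree's designated field center.  The
default factor 0.45 yields mean tortuosities near 2 with tails past 3;
larger factors push the distribution toward the 1–7 range observed across
real cells.  At factor 0 the perturbation and attraction vanish entirely,
so every soma-to-tip path is exactly collinear (tortuosity ≡ 1) — a
degenerate, spatially overlapping arbor that exists purely as an analytic
calibration case.  Ground truth (per-subtree tip ids, field centers, axon
tips, designed radii and path lengths) is emitted alongside the geometry.
`scrambled_twin` permutes tip coordinates across subtrees while keeping
topology and per-subtree counts — a positive control that sits inside the
bootstrap's own null.

What passing tests on synthetic data do **not** show: the generator has
no anastomoses-avoidance artifacts, no hand-like thick segments, no
tracing noise or missing branches, and its tip clusters are isotropic
Gaussians rather than sheet-like real fields.  Results on real
reconstructions therefore still depend on tracing quality in ways the
suite cannot probe.

## Statistical reporting

Group comparisons across cell types are descriptive conveniences
delegated to standard routines: Levene's test at α = 0.05 gates one-way
ANOVA vs Kruskal–Wallis (the homoscedasticity criterion is stated in the
underlying protocol, the specific gate test is this package's choice, and
is recorded in the output), with Tukey HSD pairwise results rendered as
compact letter displays.  Pipeline outputs are a pure function of inputs,
config, and seeds; provenance (config hash, seed, versions, skip log) is
written with every run.

## Problem sizes in the shipped tests

The suite exercises neurons of ~1,000–1,500 nodes (60–130 tips), MST
references with ~60 branch points (carrier counts a few hundred), 2,000
bootstrap iterations for power checks, and 400 scrambled twins × 399
iterations for null calibration; oracle equivalence runs on trees ≤ 50
nodes (Sholl), ≤ 7 carriers × 100 seeds (MST), and 1,000 random radius
triples (Rall).  These sizes were chosen to keep the full suite fast on a
single CPU while leaving every structural regime (multi-axon trunks,
multifurcations, degenerate clouds) represented.
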