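# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `leafcloud`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Scope and data model

The unit of analysis is a *branch sample*: an (n × 3) point cloud in
meters, optionally with a binary semantic column (0 = branch wood,
1 = leaf) and an instance-id column (leaf number, −1 for branch points).
Semantic labels are treated as input — produced by manual annotation or
an external point classifier — because branch/leaf classification is a
separate learning problem outside this package's scope. Coordinates are
right-handed with z as the zenith (up) axis; internal lengths are meters,
reported traits are degrees / cm / cm².

## Preprocessing

* **Statistical outlier removal.** A point is kept iff its mean distance
  to its k nearest neighbors is ≤ mean + r·std of those per-point means.
  Defaults k = 16, r = 1.0 (conventional values for terrestrial scans;
  the source method names no numbers). Note that on a *bounded* uniform
  grid the per-point means differ at corners for k ≥ 3, so "uniform data
  loses nothing" holds only for small k.
* **Voxel thinning** at 0.003 m, the scanner's nominal point spacing.
  The representative point is the voxel *centroid* (not the voxel
  center), preserving surface position; labels are decided by majority
  vote (semantic ties → branch, instance ties → smallest id).
* **Farthest point sampling** to 2048 points preserves branch structure
  at a fixed budget. The start point is chosen by a seeded RNG (the only
  randomness in the pipeline); for fixed seed the output is
  deterministic, and the sample's minimum pairwise distance is
  non-increasing in the sample size.
* **Normalization** centers the centroid at the origin and scales
  isotropically so the largest axis-aligned extent equals 2 m. Isotropy
  preserves angles and shape ratios, so inclination is unaffected. The
  (center, scale) transform is recorded; the round trip is exact to
  < 1e−9 m (measured ~1e−16).

## Single-leaf segmentation

Flat-kernel mean shift with bandwidth = `radius`: seeds iterate to the
mean of the points within the radius until displacement < 1e−4 m (cap 300
iterations). Seeds are centroids of an occupied bin grid with cell size =
radius, anchored at the cloud's **minimum corner**, which makes the whole
computation exactly translation-equivariant (verified to 1e−15);
exhaustive seeding is available and agrees on well-separated data.
Converged modes closer than the radius are merged — the mode with more
supporting points wins, ties broken toward the lexicographically smaller
center — and every point joins its nearest surviving mode. Clusters with
fewer than `min_points` (default 10) are dissolved and reassigned:
fragments of occluded leaves otherwise spawn spurious instances.

The bandwidth plays the role of the circumscribed-sphere radius of a
typical leaf. At pear scale, 35 mm over-fragments large leaves, 55 mm
merges adjacent small ones, and 45 mm balances the two; the cluster count
is monotonically non-increasing across {35, 45, 55} mm on the synthetic
suite. The implementation is deterministic (no RNG anywhere) and is
cross-checked against scikit-learn's MeanShift on separated blobs in the
test suite.

## Trait estimation

All stages run on the leaf instance in original (denormalized) meters,
after **moving-least-squares smoothing**: each point is projected onto an
order-2 bivariate polynomial fitted in its local tangent frame over a
12 mm radius (4× the voxel size); points with insufficient support pass
through unchanged. On a noise-free plane MLS is an exact fixed point; on
σ = 1 mm jitter it removes ≥ 50% of the RMS roughness.

**Inclination.** The leaf plane is fitted by *orthogonal* (total) least
squares via eigen-decomposition of the point covariance — z-on-xy
regression would be ill-posed for steep leaves. The normal's sign is
fixed to a non-negative z component, making α = arccos |r·ẑ| well defined
in [0°, 90°].

**Midrib walk.** The farthest point pair of the leaf is taken as base P
and tip Q (which is which does not matter). The walk repeatedly scores
the k nearest remaining neighbors of the current point b by
D = ‖n−b‖ + ‖n−Q‖ and moves to the minimizer, removing it from the
working cloud; Q is never removed, so termination within n steps is
guaranteed. Ties on D break toward the smaller point index. Two design
points matter in practice:

* *Operating spacing.* The k = 8 window only discriminates direction when
  neighbor spacing is ~3 mm. At raw scan density (~1–2 mm) D differences
  between lateral options vanish and the walk wanders, inflating lengths.
  The walk therefore runs on a 3 mm voxel-thinned copy of the smoothed
  leaf (`walk_voxel`, set 0 to disable), with P, Q appended so the
  endpoints are always members. This mirrors the thinning the full
  pipeline applies anyway.
* *Projection.* The walk is projected onto S_vein (through P and Q,
  ⊥ S_leaf) before summing. For a drooping leaf the midrib's own plane
  nearly coincides with S_vein, so the projection preserves the midrib
  arc while cancelling the walk's lateral zigzag — this is why the
  length estimate is robust (≤ 3.6% mean relative error on the synthetic
  suite) even though the walk itself is greedy.

**Width.** M is the leaf point farthest from S_vein — a boundary point of
the widest cross-section. Its partner L is the nearest point of the
*projected* midrib: because L lies exactly in the vein plane, the
M→L span covers the full half width regardless of how far the raw walk
strayed sideways (using raw walk points here produces half-width errors
up to ±60%). The M→L walk is projected onto S (through M, ⊥ S_leaf and
S_vein) and doubled. Known bias: S_vein is anchored on the *sampled*
farthest pair, whose ~1 mm lateral sampling offset tilts the plane, and
M = argmax always picks the wider-reading side — a one-sided ~+4% bias
for ~3–5 cm leaves. Asymmetric leaves report twice the wider half, by
construction.

**Area.** The surface is meshed by projecting each point's neighborhood
(radius 5× the mean 6-NN spacing, ≤ 100 points) onto its local tangent
plane and Delaunay-triangulating; a triangle enters the mesh only if all
three of its vertices propose it, which keeps the mesh overlap-free and
consistent (a deterministic 1e−7-scale jitter breaks cocircular ties on
regular grids). Triangle areas are summed with Heron's formula, clamping
tiny negative radicands; Heron agrees with the cross-product oracle to
1e−10 relative on random meshes. Guards: triangles with an edge longer
than `mu` = 5× the local 6-NN spacing are rejected (this keeps one-sided
boundary fans but rejects chords bridging dropout holes — verified on a
leaf with a 30% spherical-cap dropout), as are triangles whose normal
deviates > 60° from their vertex normals (fold-overs). Interior-angle
limits exist as options but default to off: Heron's sum is insensitive to
sliver *shape*, while thin boundary triangles carry real area, and
pruning them biases the estimate down by ~10% at scan spacing. Leaf area
remains an intrinsic slight *under*-estimate (the mesh cannot extend past
the outermost samples): ~5% at 25 points/cm².

## Synthetic generator

A leaf is a ruled surface over a quadratic Bézier midrib that droops out
of the leaf plane (middle control point lifted by `droop`·chord), with
lateral offsets along a fixed width direction and profile
w(s) = w_max · sin(π s^q)^p — zero at base and tip, peaking at arc
position `s_mid` (default 0.4: ovate, widest below the middle, like a
pear leaf). An optional dihedral fold rotates the two half-blades about
the local tangent. Ground truth per leaf:

* length — midrib arc length by 4096-point quadrature;
* width — max of the width profile (intrinsic, across the surface);
* area — fine-grid surface quadrature (doubling the grid changes the
  value by < 0.1%, tested);
* inclination — total-least-squares plane normal of a dense,
  area-uniform, deterministic surface grid of the posed leaf (consistent
  with what a perfect estimator could recover).

Truth depends only on the spec, never on the sampling seed. Points are
drawn area-uniformly (inverse-CDF in arc position, uniform across the
local width) at 25 points/cm² by default — ~2 mm effective spacing,
matching a close-range terrestrial scan (nominal 3 mm spacing at 10 m,
scans at ~5 m). Gaussian jitter (default σ = 0.5 mm when simulating scan
noise) and per-leaf spherical-cap dropout emulate registration error and
occlusion incompleteness.

Branches are slightly bent 4 mm-radius cylinders sampled at 3 mm, with
leaves attached along the axis in an alternating sideways (phyllotaxis-
like) pattern; blade sizes default to pear scale (length 4–12 cm, width
2–7 cm via an aspect ratio of 0.45–0.62, clipped). Pairwise leaf-centroid
separation is recorded; a minimum separation can be *requested*
(placement retries with fresh jitter, erroring out after `max_retries`),
which the well-separated 12-leaf test fixture uses (1.1 m branch, tilts
10–60°, separation ≥ 95 mm). Realistic crowded branches have centroid
separations of 2–7 cm, which is exactly why mean shift mis-segments some
leaves at any fixed radius.

What the generator does **not** emulate: petioles as distinct structures,
serrated margins, leaf-on-leaf contact, lidar beam divergence, intensity,
registration ghosting, and within-canopy occlusion shadows beyond the
spherical-cap model. Passing tests therefore demonstrate the geometry of
the estimators, not performance on field scans.

## Numerical choices and degenerate inputs

* Plane fit rejects collinear inputs (relative eigenvalue threshold
  1e−12); S_vein construction rejects a base–tip axis parallel to the
  leaf normal; the S plane rejects parallel leaf/vein planes.
* Farthest-pair ties break toward the lexicographically smallest ordered
  pair; mode-merge ties toward the lexicographically smaller center;
  walk ties toward the smaller point index. All stages are deterministic
  given the config and seed.
* Heron radicands are clamped at zero; degenerate (collinear) triangles
  contribute zero area.
* Leaves that collapse or fail any stage produce a per-leaf failure
  record (`status` column) with the instance id attached; the pipeline
  continues with the remaining leaves.
* `estimate_phenotype` requires ≥ 30 points per leaf (below that no
  stable plane or walk exists at 3 mm spacing).

## Problem sizes

The test suite and acceptance script use: 50-leaf recovery suite
(~250–1300 points per leaf), branches of 10–14 leaves (~9–11 k points),
100 random meshes, 1000-point planar grids, 3000-point spheres, and
400-point analytic arcs. A full `pytest` run takes ~1 minute; the
acceptance script ~30 s.

## Known limitations

* Leaf length includes whatever the instance contains — if the petiole
  is part of the instance, it is part of the length (the farthest-pair
  rule does not separate lamina from petiole).
* Width assumes approximate bilateral symmetry; strongly curled leaves
  violate the inclination/width geometry (the paper-scale error budget
  here assumes moderate droop and fold).
* Area is a slight systematic underestimate at scan density; no
  correction factor is applied.
* Mean shift with any fixed radius over- or under-segments leaves whose
  size departs strongly from the radius; incomplete (dropout) leaves
  below `min_points` are absorbed into neighbors by design.
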