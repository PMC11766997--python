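# Methods

## Scope and coordinate conventions

The package reduces a terrestrial LiDAR scan of an orchard block to
per-tree geometry and validates it against manual measurements. All
coordinates are meters in a right-handed frame: X along the tree rows, Y
across rows, Z up. Raw scans acquired with the sensor mounted sideways are
reoriented by a two-phase rotation — counterclockwise about Z by θ, then
about Y by φ. The Y rotation uses the clockwise sign convention (−sin φ in
the first row of the matrix), which maps +X to +Z at φ = 90°; a
`clockwise_y=False` flag selects the standard counterclockwise convention.
Both angles default to 90°, the pose of a side-mounted scanner.

## Processing chain

1. **Radius outlier removal.** A point is kept iff at least `min_neighbors`
   *other* points lie within `radius`. Decisions are simultaneous — counts
   are evaluated on the original cloud, never sequentially — so the result
   is independent of point order. The conventional defaults
   (`min_neighbors=32`, `radius=0.01` m) suit dense field scans from a
   ~300k points/s sensor where real surfaces have dozens of returns per
   square centimeter; the sparser desk-scale synthetic clouds use
   `min_neighbors=5`, `radius=0.3` m (the pipeline-config defaults). An
   optional statistical filter (mean k-NN distance > cloud mean +
   `std_ratio`·sd) is off by default and enabled in the desk-scale pipeline
   (`sor_k=20`, `std_ratio=2`) to catch near-surface stragglers the radius
   filter passes at low density.
2. **Voxel downsampling.** Space is cut into cubes of edge `voxel` anchored
   at the origin; each occupied cube is replaced by the centroid of its
   members. Output order is lexicographic in the voxel index, making runs
   reproducible.
3. **Ground segmentation.** RANSAC: 3-point candidate planes, inlier count
   at `dist_threshold` (default 0.05 m, 1000 iterations, seeded), total
   least-squares refit on the winning inliers, normal oriented toward +Z.
   Because ground returns are a small minority of an orchard scene, the
   pipeline fits on *ground seeds* — the lowest return of each 0.5 m x-y
   cell — which makes an all-ground sample overwhelmingly likely at any
   canopy density. Points more than the threshold above the plane form the
   canopy cloud; points more than the threshold *below* it are treated as
   sensor artifacts and excluded from height estimation.
4. **Row and tree clustering.** Rows first: exact 1-D DBSCAN on the
   y-coordinate (core points chain when consecutive core values are within
   `row_eps`), which sparse stragglers between rows cannot bridge. Then,
   within each row, 2-D DBSCAN on the x-y projection at tree scale
   (`eps=0.4` m, `min_pts=10` — about half the clear gap between ~2.5 m
   crowns planted 3.2 m apart). The tree stage snaps projections to an
   eps/4 grid and clusters the occupied cells (labels broadcast back to
   points), which bounds memory on arbitrarily dense clouds; a genuine
   canopy region occupies far more cells than `min_pts`, so the
   cell-level core test coincides with the point-level one at tree
   scale. The DBSCAN implementation fixes the border
   tie-break: clusters grow breadth-first from the lowest-index unvisited
   core point, so a border point reachable from two clusters joins the
   first that visits it, deterministically. A `single-pass` strategy
   (one 2-D clustering, no row stage) is available. Trees are labeled
   `R<row>T<position>` ordered by centroid y then x.

## Per-tree features

- **Height** `H_tree = H_max − H_min`. `H_max` is the top of the tree's own
  cluster; `H_min` is the lowest return inside the tree's x-y footprint
  (grown by 0.1 m) in the full preprocessed cloud, i.e. a near-ground base.
  Two erroneous-point guards apply before `H_max` is read: returns split
  from the cluster's z-profile by a gap larger than `max_z_gap` (default
  0.15 m) are trimmed, and an apex return must be corroborated by at least
  `min_top_support=2` neighbors within 0.12 m — an uncorroborated single
  return floating above the canopy is noise, not the tree top. A
  `height_from_plane` flag references the base to the fitted ground plane
  instead of the lowest return.
- **Canopy volume** is the bounding box of the cluster above a z-floor
  (`canopy_floor=0.3` m above the tree's base, excluding the trunk), with
  the cross-row (Y) extent replaced by a field-measured width when one is
  supplied — a single-sided scan under-represents cross-row depth. On a
  filled ellipsoid canopy the box volume converges to `D1·D2·H_c` as
  density grows, exactly `6/π` times the ellipsoid comparator
  `CV_m = (π/6)·D1·D2·½[(Ht1−Hs1)+(Ht2−Hs2)]`; the two estimators
  intentionally measure different things (occupied box vs idealized
  ellipsoid) and are compared through the agreement statistics, not forced
  to coincide. The two (Ht, Hs) pairs are treated symmetrically as the
  canopy's vertical extent seen from two positions; field protocols
  sometimes describe the second pair ambiguously, and the symmetric
  reading is the one under which the formula reduces to the ellipsoid
  volume when both extents agree.
- **Spacing.** Tree spacing is the planar (x-y) distance between
  consecutive tree centroids within a row; row spacing defaults to the
  planar distance between row mean centroids, with a `tree-to-tree` mode
  that averages distances between opposite trees of consecutive rows. The
  two modes agree exactly on symmetric layouts and differ when rows are
  staggered; row-centroid is the default because it is insensitive to
  pairing choices.

## Agreement statistics

For paired sensor estimates x and manual measurements y (d = x − y, so
negative bias = sensor underestimation): r², RMSE, MAE, bias, sample sd of
differences s_d (n−1), the 95% CI `d̄ ± t*(n−1)·s_d/√n`, Lin's CCC with
population (1/n) variances (a `sample_var` flag switches conventions), and
the two-sided paired t-test. Two deliberate conventions: the default r²
denominator centers the measured values on the *sensor* mean (the
convention used in the validation context this package targets;
`conventional=True` restores the textbook measured-mean form), and MAE
takes absolute differences so MAE ≥ |bias| always.

The exact identity `RMSE² = d̄² + (n−1)/n·s_d²` is asserted on every
report. Inverted, it reconstructs s_d, CI and RMSE from a printed
(bias, t, n) summary row — useful for auditing published tables. Note one
boundary case this audit exposes: bias −0.08 m with t = −3.49 at n = 6
implies RMSE = 0.0950 m, which sits exactly on the 2-decimal rounding
boundary.

## Synthetic orchard generator

Each scene is the union of a planar (optionally sloped) ground sheet,
per-tree trunk cylinders, and filled canopy ellipsoids centered above the
trunks (vertical semi-axis = half the canopy height), plus isotropic
Gaussian range noise and uniform outliers in the inflated bounding volume.
Labels (ground / tree index / outlier) and the matching manual
ground-truth table (heights, crown diameters, canopy reference heights,
planted spacings) are emitted alongside the cloud. Randomness is a single
seed expanded into fixed per-component substreams (layout, ground, noise,
outliers, one per tree), so identical specs give byte-identical scenes.

Defaults emulate the target field layout: 2 rows × 15 trees, 3.2 m tree
spacing, 3.4 m row spacing, heights uniform in 2.5–3.55 m, crown diameters
2.2–2.5 m, 0.5 m trunks, noise σ = 0.01 m (within a ±3 cm-accuracy
sensor). Point density is a desk-scale choice, not a sensor property:
canopy density defaults to 800 points/m³ so that (a) the expected apex
sampling deficit `c·√(4/3N)` stays well under the 5 cm height tolerance
used in validation and (b) the per-tree centroid standard error
(~σ_x/√N ≈ 1 cm) keeps spacing errors small relative to the same
tolerance. The replicate detection study runs at 80 points/m³, enough for
DBSCAN cores (~80 projected neighbors within eps) while keeping 100
replicates to tens of seconds.

The generator does **not** emulate occlusion or self-shadowing, beam
divergence/footprint, intensity, leaf/branch architecture, multi-scan
registration error, or understory vegetation. Passing recovery tests on
these scenes therefore demonstrates the correctness of the geometry and
statistics pipeline under sensor-level noise and sparse outliers — not
robustness to canopy self-occlusion or real foliage structure, which field
deployments must assess separately.

## Numerical choices and degenerate inputs

- Rotation matrices are built from closed-form sines/cosines; orthonormality
  holds to 1e-12 and pairwise distances to 1e-9.
- The k-d range query returns indices in sorted order; boxes are closed
  (boundary points included); inverted boxes raise.
- Voxel grids are anchored at the origin; points exactly on a cube face
  belong to the cube of their `floor(p/voxel)` index.
- Empty clouds: filters pass them through; feature extractors raise.
- Plane fitting requires ≥ 3 non-collinear points; an all-collinear sample
  set raises a degeneracy error rather than returning an arbitrary plane.
- Zero-variance differences make the paired t-test undefined (raised as
  `ZeroDivisionError`); `build_report` records NaN for t and p in that
  case while still reporting the error metrics and a collapsed CI.
- DBSCAN label numbering follows first-visited order (stable under point
  permutation up to renumbering); `dbscan_1d` numbers clusters by
  increasing value.

## Known limitations

- The bounding-box volume is sensitive to single extreme returns; the
  z-gap and apex-support guards mitigate but do not eliminate this, and
  convex-hull/alpha-shape estimators are out of scope by design.
- Ground removal assumes a single dominant plane; terraced or strongly
  undulating ground would need piecewise fitting.
- Row clustering assumes rows parallel to X with a clear cross-row gap
  wider than `row_eps`; heavily interlocking canopies across rows defeat
  the 1-D row stage (use `single-pass` with care there).
- With uniform outliers, a stray return landing within the apex-support
  radius of a canopy top is geometrically indistinguishable from canopy
  and bounds the achievable height accuracy at desk-scale densities.
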