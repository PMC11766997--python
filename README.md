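# orchardscan

Orchard tree morphometry from 3D LiDAR point clouds.

`orchardscan` turns terrestrial LiDAR scans of fruit-tree rows into per-tree
geometric features — tree height, canopy volume, tree spacing and row
spacing — and quantifies how well those sensor estimates agree with manual
field measurements. It is aimed at precision-agriculture and plant-phenotyping
work where a scan of an orchard block must be reduced to a tidy per-tree
table and validated against tape-measure ground truth.

## What it computes

**Processing chain** (each stage is an importable function and a CLI
subcommand): two-phase coordinate correction (rotation about Z by θ, then
about Y by φ in the clockwise sign convention), radius outlier removal
(drop points with fewer than *k* neighbors within radius *r*), voxel-grid
downsampling (one centroid per occupied cube), RANSAC ground-plane
segmentation seeded from per-cell lowest returns, region-of-interest
cropping through a k-d index, and DBSCAN clustering of the x-y projection
into rows and individual trees.

**Per-tree features**:

- height `H_tree = H_max − H_min` (top of the tree's cluster minus its
  near-ground base);
- canopy volume as the axis-aligned bounding box of the canopy points,
  `V = ΔX · ΔY · ΔZ`, optionally substituting a field-measured cross-row
  width for ΔY when only one side of the row was scanned;
- the manual ellipsoid comparator computed from two-position field
  measurements, `CV_m = (π/6) · D1 · D2 · ½[(Ht1−Hs1) + (Ht2−Hs2)]`;
- centroids `C = (1/n) Σ (x_i, y_i, z_i)` and planar center-to-center
  tree/row spacings `d = √((x2−x1)² + (y2−y1)²)`.

**Agreement statistics** for paired sensor (x) vs measured (y) values:
r², RMSE, MAE, bias `d̄ = mean(x−y)`, the 95% paired-t confidence interval
`d̄ ± t*·s_d/√n`, Lin's concordance correlation coefficient
`CCC = 2ρσxσy / (σx² + σy² + (µx−µy)²)`, and the paired t-test
`t = d̄/(s_d/√n)`. The three error statistics satisfy the exact identity
`RMSE² = d̄² + (n−1)/n · s_d²`, which also lets a published summary row be
audited from its printed (bias, t, n) alone (`reconstruct_from_bias_t`).

**Synthetic orchards**: because field scans are rarely shareable, the
package generates labeled synthetic scenes — parallel tree rows along X,
trunk cylinders, filled canopy ellipsoids, a ground plane, Gaussian range
noise and uniform outliers — with exact per-point labels and the matching
manual ground-truth table, so every stage can be validated end to end.

## Worked example

```bash
python examples/simulate_and_measure.py
```

generates a 2 × 6-tree orchard (3.2 m tree spacing, 3.4 m row spacing,
1 cm range noise, 1% stray returns) and runs the full pipeline:

```
scene: 82305 points, 12 trees
detected 12 trees in 2 rows
  tree  est. height  true height  canopy vol
  R1T1        3.47m        3.46m      16.0m3
  R1T2        3.46m        3.46m      18.1m3
  ...
mean tree spacing 3.20 m (planted 3.2)
row spacing       3.40 m (planted 3.4)
height error: mean +0.002 m, worst 0.015 m
```

Every estimated height tracks its generating value to a few centimeters and
the planted grid is recovered; `examples/agreement_statistics.py` shows the
validation battery and the summary-audit utility, and
`examples/preprocess_and_segment.py` steps through the processing chain
stage by stage.

The same functionality is exposed as a CLI:

```bash
orchardscan simulate --rows 2 --trees-per-row 6 --out sim/
orchardscan run sim/cloud.pcd --ground-truth sim/ground_truth.csv --out results/
orchardscan validate pairs.csv --sensor-col sensor --measured-col measured
```

## File formats

Clouds: ASCII PCD, ASCII PLY, XYZ/CSV (x,y,z per line, meters). Ground
truth: CSV with columns `tree_id, measured_height, D1, D2, Ht1, Hs1, Ht2,
Hs2, row_index, position_in_row` plus constant `tree_spacing` /
`row_spacing` columns. Metrics and reports are written as CSV and JSON; the
resolved pipeline configuration is saved in YAML next to every run's
outputs.

## Documentation

`docs/methods.md` describes the model assumptions, parameter defaults,
what the synthetic generator does and does not emulate, and the numerical
choices (tie-breaks, tolerances, degenerate-input behavior).
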