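"""Step through the processing chain stage by stage.

Demonstrates the two-phase coordinate correction (the sensor acquires
rotated 90 degrees about Z, then the cloud is rotated about Y), radius
outlier removal, voxel downsampling, RANSAC ground-plane segmentation
and DBSCAN tree clustering on a small synthetic scene.
"""

import numpy as np

from orchardscan import (
    OrchardSpec,
    RotationSpec,
    apply_sensor_pose,
    cluster_trees,
    fit_ground_plane,
    generate_orchard,
    radius_outlier_removal,
    remove_ground,
    transform_coordinates,
    voxel_downsample,
)
from orchardscan.segmentation import ground_seed_indices

spec = OrchardSpec(n_rows=1, trees_per_row=3, noise_sigma=0.01,
                   outlier_fraction=0.02, seed=7)
world, truth, labels = generate_orchard(spec)

# emulate the raw acquisition pose, then correct it
pose = RotationSpec(theta_deg=90, phi_deg=90)
raw = apply_sensor_pose(world, pose)
corrected = transform_coordinates(raw, pose)
print(f"pose correction residual: {np.abs(corrected.points - world.points).max():.2e} m")

cloud, removed = radius_outlier_removal(corrected, min_neighbors=5, radius=0.3)
print(f"radius filter removed {removed.sum()} of {len(removed)} points")

cloud = voxel_downsample(cloud, voxel=0.02)
print(f"{len(cloud)} points after 2 cm voxel downsampling")

seeds = ground_seed_indices(cloud, cell=0.5)
plane = fit_ground_plane(cloud.select(seeds), dist_threshold=0.05,
                         n_iterations=500, seed=1)
print(f"ground plane normal {np.round(plane.normal, 3)}, "
      f"{len(plane.inliers)} seed inliers")

canopy = remove_ground(cloud, plane)
clusters = cluster_trees(canopy, eps=0.4, min_pts=10)
print(f"{clusters.n_clusters} trees found "
      f"(noise points: {(clusters.labels == -1).sum()})")
# each cluster id maps to a stable tree label, R<row>T<position>
print("tree ids:", sorted(clusters.tree_of_cluster.values()))
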