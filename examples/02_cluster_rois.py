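"""Find regions with significant evoked activity by cluster permutation.

A toy 20x20 source mesh carries a planted activation patch in the "image"
condition; the "fixation-cross" condition is pure noise.  The spatiotemporal
cluster permutation test (SCPT) controls the family-wise error over all
vertex x time points, and accepted clusters are partitioned into ROIs along
the mesh's atlas labels (a label needs >= 15% significant vertices).
"""

import numpy as np

from fixnet import scpt
from fixnet import synthgen as sg

mesh = sg.grid_mesh(20, 20, spacing=6.2)
patch = np.array([85, 86, 87, 105, 106, 107, 125, 126, 127, 145, 146, 147])
planted = sg.PlantedCluster(patch, time_window_ms=(40, 160), amplitude=8.0)

image, cross = sg.simulate_vertex_fra(mesh, planted, n_runs=30, noise_sd=1.0,
                                      seed=7)
contrast = scpt.make_contrast(image, cross)

result = scpt.cluster_test(contrast, window_ms=(0, 200), n_permutations=500,
                           alpha=0.05, seed=7)
surviving = scpt.filter_clusters(result, min_vertices=5, min_duration_ms=20.0)
rois = scpt.partition_rois(surviving, mesh.labels, min_fraction=0.15)

print(f"{len(result.clusters)} cluster(s) found, "
      f"{len(surviving.clusters)} survive the size/duration/significance rules")
for cl in surviving.clusters:
    overlap = np.intersect1d(cl.vertex_set, patch).size / patch.size
    print(f"  cluster: {cl.vertex_set.size} vertices, mass {cl.mass:.1f}, "
          f"p = {cl.p:.4f}, overlap with planted patch {overlap:.0%}")
for roi in rois:
    print(f"ROI {roi.label}: {roi.member_vertices.size} significant vertices "
          f"({roi.significant_fraction:.0%} of the label)")
# The p-value is permutation-based (sign flips of whole runs), so a cluster
# at p ~ 0.002 beat essentially every one of the 500 shuffled datasets.
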