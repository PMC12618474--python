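"""Build voxel-to-ROI connectomes from resting-state series.

Generates a small synthetic cohort, splits one subject's rest series into
contiguous segments, and computes the K-channel voxel-to-ROI connectome
that serves as the network's input, plus the K x K ROI connectome used as
comparison features downstream.
"""

import numpy as np

from voltaskgen.connectome import (
    roi_to_roi_connectome,
    split_timeseries,
    upper_triangle,
    voxel_to_roi_connectome,
)
from voltaskgen.synthcohort import SyntheticCohortSpec, generate_cohort

spec = SyntheticCohortSpec(n_subjects=2, n_timepoints=240, seed=0)
cohort = generate_cohort(spec)
ts = cohort.rest[0]

segments = split_timeseries(ts, segment_length=120)
print(f"rest series: {ts.n_timepoints} timepoints over {ts.grid.n_mask} "
      f"gray-matter voxels -> {len(segments)} segments of 120")

conn = voxel_to_roi_connectome(segments[0], cohort.atlas)
print(f"voxel-to-ROI connectome: shape {conn.shape} "
      f"(K={spec.n_components} channels on the {spec.shape} grid)")
in_mask = conn[:, ts.grid.mask]
print(f"correlation range inside the mask: "
      f"[{in_mask.min():.3f}, {in_mask.max():.3f}]  (Pearson r, by construction in [-1, 1])")

roi_conn = roi_to_roi_connectome(ts, cohort.atlas)
feats = upper_triangle(roi_conn)
print(f"ROI-to-ROI connectome: {roi_conn.shape[0]}x{roi_conn.shape[1]} matrix, "
      f"{feats.size} upper-triangle features (K(K-1)/2)")
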