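"""Build the training targets and input channels for the network stages.

The ROI target is a binary in-box test (marker bounding box + 100 mm margin);
the landmark target assigns classes 1-6 to points within 10 mm of each
marker; the input features are the raw coordinates plus their min-max
normalization over the cloud's bounding box.
"""

import numpy as np

from pelvimark.preprocessing import (
    build_point_features,
    downsample_uniform,
    label_landmark_regions,
    label_points_in_box,
    roi_box_from_markers,
)
from pelvimark.synthetic import ScanRecipe, generate_scan, sample_subject

cloud, landmarks = generate_scan(ScanRecipe(shape=sample_subject(2), n_points=40_000, seed=5))

box = roi_box_from_markers(landmarks, margin_mm=100.0)
roi = label_points_in_box(cloud, box)
print(f"ROI box bounds (mm):\n{np.round(box.bounds, 0)}")
print(f"pelvic fraction of the scan: {roi.labels.mean():.2f}")

scan = downsample_uniform(cloud, 16_384, seed=0)
regions = label_landmark_regions(scan, landmarks, radius_mm=10.0)
counts = np.bincount(regions.labels, minlength=7)
print("points per landmark class (10 mm radius at 16,384-point density):", counts[1:])

feat = build_point_features(scan)
print("feature channels:", feat.features.shape[1], "(raw xyz + bbox-normalized xyz)")
print("normalized-channel range:", feat.features[:, 3:].min(), "-", feat.features[:, 3:].max())
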