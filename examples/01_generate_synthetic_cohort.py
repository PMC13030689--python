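"""Generate a small synthetic cohort of pelvic surface scans.

Each scan is a point cloud in scanner coordinates (mm) with six ground-truth
posterior landmarks (PSIS_L/R, IC_L/R, L1, L4).  Repeats within a visit share
the subject's shape and differ by pose, sensor noise and small landmark
placement jitter.
"""

import numpy as np

from pelvimark.synthetic import generate_dataset

records = generate_dataset(
    n_subjects=3, visits=1, repeats_per_visit=2, postures=("P1", "P2"), seed=0
)
print(f"{len(records)} scans (3 subjects x 1 visit x 2 repeats x 2 postures)")
for rec in records[:4]:
    extent = rec.cloud.positions.max(axis=0) - rec.cloud.positions.min(axis=0)
    print(
        f"  {rec.cloud.scan_id}: {rec.cloud.n_points} points, "
        f"lateral extent {extent[0]:.0f} mm, "
        f"PSIS separation {np.linalg.norm(rec.landmarks['PSIS_L'] - rec.landmarks['PSIS_R']):.1f} mm"
    )
# The point counts fall in the tiny preset's 20k-60k range; full-resolution
# scans (200k-600k points) are available with preset="full".
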