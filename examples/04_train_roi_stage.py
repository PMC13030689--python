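"""Train the ROI segmentation stage on a miniature synthetic cohort.

A deliberately short run (a few minutes on one CPU): 6 subjects, the tiny
backbone preset, 10 epochs.  The held-out pelvic-class IoU it prints is far
below what the documented study schedule reaches (see docs/methods.md), but
the loss curve and IoU show the stage learning.
"""

import numpy as np

from pelvimark.synthetic import generate_dataset
from pelvimark.training import (
    TrainConfig,
    evaluate_roi,
    prepare_roi_samples,
    split_subjects,
    train_roinet,
)

records = generate_dataset(6, visits=1, repeats_per_visit=2, postures=("P1", "P2"), seed=3)
train, test = split_subjects(records, ratio=0.8, seed=0)
cfg = TrainConfig(epochs=10, batch_size=8, learning_rate=3e-3, seed=0)

model, history = train_roinet(train, cfg)
print("train loss per epoch:", [round(x, 3) for x in history.train_loss])
print("best epoch by validation loss:", history.best_epoch)

metrics = evaluate_roi(model, prepare_roi_samples(test, cfg), cfg)
print(f"held-out pelvic IoU: {metrics[1]['iou']:.3f}, recall: {metrics[1]['recall']:.3f}")
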