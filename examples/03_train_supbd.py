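"""Train a small supervised super-resolution localizer.

A demonstration-scale run: small crops, few pairs, a slim network.  The
full-scale configuration (80 x 80 windows, 64 channels, hundreds of
thousands of pairs) uses the same code with different numbers.
"""

import numpy as np

from ulmkit.grids import GridSpec
from ulmkit.localization import localization_error, pool_reports
from ulmkit.noise import NoiseSpec
from ulmkit.psf import make_psf
from ulmkit.scene import random_bubbles, synthesize_frame
from ulmkit.supbd import (
    SupBDSpec,
    SupTrainConfig,
    build_supbd,
    infer_map,
    net_extract_centers,
    train_supbd,
)
from ulmkit.training_data import build_training_set

crop_grid = GridSpec(window=24)  # small crops train fast; the net is
dataset = build_training_set(400, seed=0, grid=crop_grid)  # fully convolutional
model = build_supbd(SupBDSpec(feature_channels=12), seed=0)
config = SupTrainConfig(max_epochs=8, lr_decay_every=6, seed=0)
model, history = train_supbd(model, dataset, config)

print("training loss per epoch:", [f"{l:.5f}" for l in history.train_loss])
print("validation loss per epoch:", [f"{l:.5f}" for l in history.val_loss])
print(f"best epoch: {history.best_epoch}")

# apply to an unseen frame (any window size works)
grid = GridSpec(window=40)
psf = make_psf(400, 280, 0)
rng = np.random.default_rng(9)
reports = []
for _ in range(5):
    bubbles = random_bubbles(0.5, grid, rng)
    if len(bubbles) == 0:
        continue
    frame, truth = synthesize_frame(bubbles, psf, NoiseSpec(0.15), grid, rng)
    heat = infer_map(model, frame.astype(np.float32))
    # a demonstration-scale model emits dim center blobs (peaks well below
    # 1), so the example thresholds relative to each map's own maximum; a
    # fully trained model saturates its peaks and uses the default 0.5
    detections = net_extract_centers(heat, grid, min_peak=0.5 * float(heat.max()))
    reports.append(localization_error(truth, detections, gate_um=psf.fwhm_minor_um / 2))
pooled = pool_reports(reports)
print(f"held-out E_c = {pooled.E_c_um:.1f} um "
      f"({pooled.n_detections} detections / {pooled.n_truth} bubbles)")
# Expect a large E_c and spurious detections here: a minute of training on
# 400 small crops shows the machinery (loss descent, checkpoint selection,
# fully convolutional inference) but nowhere near converged localization.
# Accuracy improves steadily with pairs, channels, and epochs -- the loss
# curves above are still dropping when this run stops.
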