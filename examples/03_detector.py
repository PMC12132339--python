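"""Train the heatmap-regression behavior detector on rendered frames.

Renders grayscale frames (Gaussian blobs at the keypoints plus the barrier
line), places a point label at the nose on attending frames, trains the
small fully-convolutional network, and scores held-out frames against the
planted labels.
"""

from dataclasses import replace

import numpy as np

from fomopipe.detect import classify_frames, make_heatmap_targets, train_detector
from fomopipe.simulate import SimConfig, gen_frames, gen_keypoints, gen_schedule

cfg = SimConfig(seed=3, n_trials=4, habituation_s=10.0, p_trial_attend=1.0)
sched = gen_schedule(cfg)
_, truth = gen_keypoints(cfg, sched)
att = truth.attending_frames

rng = np.random.default_rng(0)
pos = rng.choice(np.nonzero(att)[0], 120, replace=False)
neg = rng.choice(np.nonzero(~att)[0], 120, replace=False)
idx = rng.permutation(np.concatenate([pos, neg]))
train_idx, test_idx = idx[:160], idx[160:]

def render(ix):
    sub = replace(truth.clean_track, coords=truth.clean_track.coords[ix])
    return gen_frames(sub, cfg, attending=att[ix])

train_stack, train_labels = render(train_idx)
test_stack, _ = render(test_idx)
targets = make_heatmap_targets(train_labels, cfg.frame_size)

model = train_detector(train_stack, targets, epochs=10, seed=0)
print("per-epoch loss:", " ".join(f"{l:.4f}" for l in model.loss_history))

eth, dets = classify_frames(model, test_stack, conf_thresh=0.5, radius_px=6.0)
pred, true = eth[:, 0], att[test_idx]
tp = int((pred & true).sum())
prec = tp / max(int(pred.sum()), 1)
rec = tp / max(int(true.sum()), 1)
print(f"held-out frames: {len(test_idx)}; precision {prec:.2f}, recall {rec:.2f}, "
      f"F1 {2 * prec * rec / (prec + rec):.2f}")
# each detection carries the predicted behavior location and its confidence
print(dets.head(3).to_string(index=False))
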