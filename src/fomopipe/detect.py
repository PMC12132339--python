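"""Supervised behavior detection by heatmap regression, and the
attending-frame / trial quantification built on it.

The detector predicts, directly from single grayscale frames, a per-class
heatmap whose local peaks mark locations where the behavior is occurring
(the approach pose-estimation methods use for keypoint localization).  Peaks
surviving non-maximum suppression are positive predictions with confidence
equal to the peak value; a frame is scored positive for a class iff it has
at least one retained detection.

Trial-level quantities follow the paradigm's analysis: per-trial attending
frame counts in three 5-s bins after cue onset, each normalized to the 5-s
pre-cue baseline count; attending/not-attending trial labels by global or
per-animal median thresholds (strict >); top/bottom-k extreme-trial
selection for aligning neural activity; and lick-bout quantification for the
formalin assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fomopipe._cnn import Adam, HeatmapNet
from fomopipe.features import trial_windows
from fomopipe.simulate import TrialSchedule

FrameLabelSet = list  # per frame: list of (behavior_class, x, y) tuples


@dataclass
class Detection:
    frame: int
    behavior_class: str
    x: float
    y: float
    confidence: float


@dataclass
class DetectorModel:
    """Trained heatmap-regression detector plus its training record."""

    net: HeatmapNet
    classes: tuple[str, ...] = ("attending",)
    loss_history: list[float] = field(default_factory=list)

    @property
    def stride(self) -> int:
        return self.net.output_stride


@dataclass
class TrialAttendance:
    """Per-trial attending-frame counts, baseline-normalized deltas, labels.

    ``table`` columns: trial, baseline, bin1..bin3 (raw counts),
    dbin1..dbin3 (bin - baseline), total_delta, total_count; after
    :func:`label_trials`: label, threshold_used, threshold.
    """

    table: pd.DataFrame

    @property
    def total_counts(self) -> np.ndarray:
        return self.table["total_count"].to_numpy()


# ---------------------------------------------------------------------------
# heatmap targets
# ---------------------------------------------------------------------------

def make_heatmap_targets(
    labels: FrameLabelSet,
    image_size: int,
    classes: tuple[str, ...] = ("attending",),
    sigma: float = 2.0,
    stride: int = 1,
) -> np.ndarray:
    """Per-frame, per-class target heatmaps at ``image_size / stride``.

    Each point label contributes an unnormalized Gaussian bump with peak 1
    at the (rounded) scaled label pixel; overlapping bumps combine by
    elementwise max, so values stay in [0, 1].
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    out_size = image_size // stride
    n = len(labels)
    targets = np.zeros((n, len(classes), out_size, out_size), dtype=float)
    half = max(int(np.ceil(3 * sigma)), 1)
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    kernel = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    for i, frame_labels in enumerate(labels):
        for cls, x, y in frame_labels:
            c = classes.index(cls)
            cx = int(round(x / stride))
            cy = int(round(y / stride))
            if not (0 <= cx < out_size and 0 <= cy < out_size):
                raise ValueError(f"label ({x}, {y}) outside image")
            x0, x1 = max(cx - half, 0), min(cx + half + 1, out_size)
            y0, y1 = max(cy - half, 0), min(cy + half + 1, out_size)
            targets[i, c, y0:y1, x0:x1] = np.maximum(
                targets[i, c, y0:y1, x0:x1],
                kernel[y0 - cy + half : y1 - cy + half, x0 - cx + half : x1 - cx + half],
            )
    return targets


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_detector(
    frames: np.ndarray,
    targets: np.ndarray,
    classes: tuple[str, ...] = ("attending",),
    epochs: int = 20,
    batch_size: int = 16,
    lr: float = 2e-3,
    loss: str = "bce",
    pos_weight: float = 20.0,
    seed: int = 0,
    encoder_channels: tuple[int, ...] = (8, 16, 16, 16),
    encoder_strides: tuple[int, ...] = (2, 2, 2, 1),
) -> DetectorModel:
    """Train the heatmap network with Adam; returns the model with its
    per-epoch mean loss curve.  ``epochs=0`` returns the initialized model
    untouched.  Deterministic given the seed.
    """
    frames = np.asarray(frames, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if frames.shape[0] != targets.shape[0]:
        raise ValueError("frames and targets must have matching first dimension")
    net = HeatmapNet(
        n_classes=len(classes),
        encoder_channels=encoder_channels,
        encoder_strides=encoder_strides,
        seed=seed,
    )
    model = DetectorModel(net=net, classes=classes)
    if epochs == 0:
        return model
    opt = Adam(lr=lr)
    rng = np.random.default_rng(seed)
    n = frames.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            losses.append(net.train_batch(frames[idx], targets[idx], opt, loss=loss, pos_weight=pos_weight))
        model.loss_history.append(float(np.mean(losses)))
    return model


# ---------------------------------------------------------------------------
# non-maximum suppression
# ---------------------------------------------------------------------------

def nms_peaks(heatmap: np.ndarray, conf_thresh: float = 0.5, radius_px: float = 16.0) -> list[tuple[float, float, float]]:
    """Greedy NMS over strict local maxima of one class heatmap.

    A candidate is a pixel strictly greater than all of its 8 neighbors
    (out-of-image neighbors count as -inf) with value >= ``conf_thresh``.
    Candidates are visited in descending confidence (ties broken row-major);
    a candidate within Euclidean distance <= ``radius_px`` of an already
    retained peak is suppressed.  Returns (x, y, confidence) triples.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    hm = np.asarray(heatmap, dtype=float)
    padded = np.full((hm.shape[0] + 2, hm.shape[1] + 2), -np.inf)
    padded[1:-1, 1:-1] = hm
    center = padded[1:-1, 1:-1]
    is_peak = np.ones_like(hm, dtype=bool)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            is_peak &= center > padded[1 + dy : padded.shape[0] - 1 + dy, 1 + dx : padded.shape[1] - 1 + dx]
    ys, xs = np.nonzero(is_peak & (hm >= conf_thresh))
    if len(ys) == 0:
        return []
    conf = hm[ys, xs]
    order = np.lexsort((xs, ys, -conf))
    kept: list[tuple[float, float, float]] = []
    for i in order:
        x, y, c = float(xs[i]), float(ys[i]), float(conf[i])
        if all((x - kx) ** 2 + (y - ky) ** 2 > radius_px**2 for kx, ky, _ in kept):
            kept.append((x, y, c))
    return kept


def classify_frames(
    model: DetectorModel,
    frames: np.ndarray,
    conf_thresh: float = 0.5,
    radius_px: float = 16.0,
    batch_size: int = 32,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Run the detector over frames; a frame is positive for a class iff it
    has >= 1 retained detection.

    Returns (ethogram, detections): ethogram is (frames, classes) bool and
    detections a DataFrame with frame/class/x/y/conf at input resolution.
    """
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    stride = model.stride
    ethogram = np.zeros((n, len(model.classes)), dtype=bool)
    rows = []
    for start in range(0, n, batch_size):
        maps = model.net.forward(frames[start : start + batch_size])
        for j in range(maps.shape[0]):
            for c, cls in enumerate(model.classes):
                for x, y, conf in nms_peaks(maps[j, c], conf_thresh, radius_px / stride):
                    rows.append((start + j, cls, x * stride, y * stride, conf))
                    ethogram[start + j, c] = True
    detections = pd.DataFrame(rows, columns=["frame", "class", "x", "y", "conf"])
    return ethogram, detections


# ---------------------------------------------------------------------------
# trial quantification
# ---------------------------------------------------------------------------

def quantify_attending(ethogram: np.ndarray, sched: TrialSchedule, fps: float) -> TrialAttendance:
    """Per-trial attending counts and baseline-normalized deltas.

    For each trial: the raw attending-frame count in the 5-s pre-cue
    baseline and in each of the three 5-s bins of the 0-15 s post-onset
    window; delta_bin = count_bin - count_baseline; total delta is the sum
    over the three bins.
    """
    eth = np.asarray(ethogram, dtype=bool)
    if eth.ndim == 2:
        eth = eth[:, 0]
    windows = trial_windows(sched.onsets_s, fps, len(eth))
    rows = []
    for i in range(windows.n_trials):
        b0, b1 = windows.baseline[i]
        base = int(eth[b0:b1].sum())
        bins = [int(eth[a:b].sum()) for a, b in windows.bins[i]]
        deltas = [c - base for c in bins]
        rows.append(
            {
                "trial": i,
                "baseline": base,
                **{f"bin{k+1}": bins[k] for k in range(3)},
                **{f"dbin{k+1}": deltas[k] for k in range(3)},
                "total_delta": sum(deltas),
                "total_count": sum(bins),
            }
        )
    return TrialAttendance(table=pd.DataFrame(rows))


def label_trials(
    counts: np.ndarray,
    mode: str = "global",
    animal_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Median-threshold attending/not-attending trial labels.

    ``mode='global'``: one threshold, the median of all counts pooled.
    ``mode='local'``: per-animal thresholds (median over that animal's
    trials across its conditions); ``animal_ids`` maps each trial to its
    animal (one animal assumed when omitted).  A trial is labeled attending
    iff its count is strictly greater than its threshold.

    Returns (labels bool array, per-trial threshold array).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("counts is empty")
    if mode == "global":
        thr = np.full(counts.shape, np.median(counts))
    elif mode == "local":
        if animal_ids is None:
            animal_ids = np.zeros(counts.shape, dtype=int)
        animal_ids = np.asarray(animal_ids)
        thr = np.empty(counts.shape)
        for a in np.unique(animal_ids):
            m = animal_ids == a
            thr[m] = np.median(counts[m])
    else:
        raise ValueError(f"unknown mode '{mode}'")
    return counts > thr, thr


def select_extreme_trials(counts: np.ndarray, k: int = 15) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the k trials with most and k with least attending frames.

    Trials are stably sorted by count (ties keep trial order): the bottom
    set is the first k and the top set the last k (in descending order), so
    the two sets are always disjoint and deterministic under ties.  Raises
    when fewer than 2k trials are available.
    """
    counts = np.asarray(counts)
    n = len(counts)
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} trials, got {n}")
    order = np.argsort(counts, kind="stable")
    bottom = order[:k]
    top = order[-k:][::-1]
    return top, bottom


def quantify_licks(ethogram: np.ndarray, fps: float, gap_frames: int = 1) -> tuple[int, float]:
    """Lick bout count and total lick duration from a binary lick ethogram.

    Bouts are maximal runs of positive frames; runs separated by fewer than
    ``gap_frames`` negative frames merge into one bout.  Duration is total
    positive frames / fps (seconds).
    """
    eth = np.asarray(ethogram, dtype=bool).ravel()
    duration = float(eth.sum()) / fps
    padded = np.concatenate([[0], eth.astype(int), [0]])
    starts = np.nonzero(np.diff(padded) == 1)[0]
    ends = np.nonzero(np.diff(padded) == -1)[0]
    if len(starts) == 0:
        return 0, 0.0
    bouts = 1
    for i in range(1, len(starts)):
        if starts[i] - ends[i - 1] >= gap_frames:
            bouts += 1
    return bouts, duration
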