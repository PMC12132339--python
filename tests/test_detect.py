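"""Detector stack: heatmap targets, NMS against an exhaustive oracle,
training behavior, and trial-level attending quantification."""

import numpy as np
import pytest

from fomopipe.detect import (
    classify_frames,
    label_trials,
    make_heatmap_targets,
    nms_peaks,
    quantify_attending,
    quantify_licks,
    select_extreme_trials,
    train_detector,
)
from fomopipe.simulate import TrialSchedule


def nms_oracle(hm: np.ndarray, conf: float, radius: float):
    """Independent exhaustive-scan + greedy-suppression reference."""
    h, w = hm.shape
    cands = []
    for y in range(h):
        for x in range(w):
            v = hm[y, x]
            if v < conf:
                continue
            strict = True
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == 0 and dx == 0:
                        continue
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and not (v > hm[yy, xx]):
                        strict = False
            if strict:
                cands.append((x, y, v))
    cands.sort(key=lambda c: (-c[2], c[1], c[0]))
    kept = []
    for x, y, v in cands:
        if all((x - kx) ** 2 + (y - ky) ** 2 > radius**2 for kx, ky, _ in kept):
            kept.append((float(x), float(y), float(v)))
    return kept


class TestHeatmapTargets:
    def test_empty_labels_zero_map(self):
        t = make_heatmap_targets([[], []], image_size=32)
        assert t.shape == (2, 1, 32, 32) and not t.any()

    def test_single_label_peak_one(self):
        t = make_heatmap_targets([[("attending", 10.0, 20.0)]], image_size=32)
        iy, ix = np.unravel_index(np.argmax(t[0, 0]), (32, 32))
        assert (ix, iy) == (10, 20) and t[0, 0, 20, 10] == 1.0

    def test_overlapping_labels_max_combined(self):
        t = make_heatmap_targets([[("attending", 10.0, 10.0), ("attending", 11.0, 10.0)]], image_size=32)
        assert t.max() <= 1.0 and t[0, 0, 10, 10] == 1.0 and t[0, 0, 10, 11] == 1.0

    def test_bad_sigma(self):
        with pytest.raises(ValueError):
            make_heatmap_targets([[]], image_size=32, sigma=0)


class TestNMS:
    def test_zero_map(self):
        assert nms_peaks(np.zeros((16, 16))) == []

    def test_single_pixel(self):
        hm = np.zeros((16, 16))
        hm[5, 5] = 1.0
        assert nms_peaks(hm) == [(5.0, 5.0, 1.0)]

    def test_close_peaks_suppressed(self):
        hm = np.zeros((32, 32))
        hm[10, 10] = 0.9
        hm[10, 10 + 7] = 0.8  # radius - 1 away
        out = nms_peaks(hm, conf_thresh=0.5, radius_px=8)
        assert out == [(10.0, 10.0, 0.9)]

    def test_subthreshold_noise_invariance(self, rng):
        hm = np.zeros((24, 24))
        hm[5, 5], hm[18, 12] = 0.9, 0.7
        base = nms_peaks(hm, conf_thresh=0.5, radius_px=4)
        noisy = hm + rng.uniform(0, 0.01, hm.shape) * (hm == 0)
        out = nms_peaks(noisy, conf_thresh=0.5, radius_px=4)
        assert [(x, y) for x, y, _ in out] == [(x, y) for x, y, _ in base]

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(100):
            hm = rng.random((12, 12))
            got = nms_peaks(hm, conf_thresh=0.5, radius_px=3)
            exp = nms_oracle(hm, 0.5, 3)
            assert got == exp


@pytest.fixture(scope="module")
def blob_fixture():
    from dataclasses import replace

    from fomopipe.simulate import SimConfig, gen_frames, gen_keypoints, gen_schedule

    cfg = SimConfig(seed=3, n_trials=2, habituation_s=10, p_trial_attend=1.0)
    sched = gen_schedule(cfg)
    _, truth = gen_keypoints(cfg, sched)
    att = truth.attending_frames
    rng = np.random.default_rng(0)
    pos = rng.choice(np.nonzero(att)[0], 30, replace=False)
    neg = rng.choice(np.nonzero(~att)[0], 30, replace=False)
    idx = np.sort(np.concatenate([pos, neg]))
    sub = replace(truth.clean_track, coords=truth.clean_track.coords[idx])
    stack, labels = gen_frames(sub, cfg, attending=att[idx])
    targets = make_heatmap_targets(labels, cfg.frame_size)
    return stack, targets


class TestTraining:
    def test_zero_epochs_returns_initialized_model(self, blob_fixture):
        stack, targets = blob_fixture
        model = train_detector(stack, targets, epochs=0)
        assert model.loss_history == []

    def test_loss_decreases(self, blob_fixture):
        stack, targets = blob_fixture
        model = train_detector(stack, targets, epochs=3, seed=0)
        assert model.loss_history[-1] < model.loss_history[0]

    def test_training_deterministic(self, blob_fixture):
        stack, targets = blob_fixture
        a = train_detector(stack, targets, epochs=2, seed=0)
        b = train_detector(stack, targets, epochs=2, seed=0)
        assert a.loss_history == b.loss_history

    def test_impossible_threshold_all_negative(self, blob_fixture):
        stack, targets = blob_fixture
        model = train_detector(stack, targets, epochs=1, seed=0)
        eth, dets = classify_frames(model, stack[:8], conf_thresh=1.0 + 1e-9)
        assert not eth.any() and dets.empty

    def test_shape_mismatch(self, blob_fixture):
        stack, targets = blob_fixture
        with pytest.raises(ValueError):
            train_detector(stack[:5], targets[:4])


class TestQuantifyAttending:
    def _sched(self, onsets):
        return TrialSchedule(onsets_s=np.asarray(onsets, dtype=float))

    def test_delta_arithmetic(self):
        fps = 2.0  # 10-frame baseline and bins
        eth = np.zeros(160, dtype=bool)
        # onset at 20 s -> frame 40: baseline [30,40), bins [40,50), [50,60), [60,70)
        eth[30:32] = True  # baseline 2
        eth[40:50] = True  # bin1 10
        eth[50:55] = True  # bin2 5
        eth[60:63] = True  # bin3 3
        ta = quantify_attending(eth, self._sched([20.0]), fps)
        row = ta.table.iloc[0]
        assert list(row[["baseline", "bin1", "bin2", "bin3"]]) == [2, 10, 5, 3]
        assert list(row[["dbin1", "dbin2", "dbin3"]]) == [8, 3, 1]
        assert row["total_delta"] == 12
        assert row["total_delta"] == row[["dbin1", "dbin2", "dbin3"]].sum()

    def test_all_negative_zero_deltas(self):
        ta = quantify_attending(np.zeros(600, dtype=bool), self._sched([10.0]), fps=10.0)
        assert (ta.table[["dbin1", "dbin2", "dbin3", "total_delta"]] == 0).all().all()

    def test_all_positive_deltas(self):
        ta = quantify_attending(np.ones(600, dtype=bool), self._sched([10.0]), fps=10.0)
        assert (ta.table[["dbin1", "dbin2", "dbin3"]] == 0).all().all()  # 50-frame bins == baseline

    def test_window_exceeding_recording_raises(self):
        with pytest.raises(ValueError):
            quantify_attending(np.zeros(100, dtype=bool), self._sched([8.0]), fps=10.0)


class TestLabelTrials:
    def test_median_threshold(self):
        labels, thr = label_trials(np.array([0, 1, 2, 3, 10, 20]), mode="global")
        assert thr[0] == 2.5 and labels.sum() == 3

    def test_all_equal_none_attending(self):
        labels, _ = label_trials(np.full(10, 7.0), mode="global")
        assert labels.sum() == 0

    def test_global_equals_local_for_single_animal(self):
        counts = np.array([3, 8, 1, 9, 4, 4])
        g, _ = label_trials(counts, mode="global")
        l, _ = label_trials(counts, mode="local")
        np.testing.assert_array_equal(g, l)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            label_trials(np.array([]))


class TestExtremeTrials:
    def test_distinct_counts(self):
        counts = np.arange(60)
        top, bottom = select_extreme_trials(counts, k=15)
        np.testing.assert_array_equal(sorted(top), np.arange(45, 60))
        np.testing.assert_array_equal(sorted(bottom), np.arange(15))
        assert not set(top) & set(bottom)

    def test_all_tied_deterministic_and_disjoint(self):
        counts = np.full(40, 5)
        t1, b1 = select_extreme_trials(counts, k=15)
        t2, b2 = select_extreme_trials(counts, k=15)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(b1, b2)
        assert not set(t1) & set(b1)
        # stable-sort oracle: bottom = earliest k, top = latest k
        np.testing.assert_array_equal(sorted(b1), np.arange(15))
        np.testing.assert_array_equal(sorted(t1), np.arange(25, 40))

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            select_extreme_trials(np.arange(20), k=15)


class TestLicks:
    def test_all_negative(self):
        assert quantify_licks(np.zeros(100, dtype=bool), fps=30.0) == (0, 0.0)

    def test_single_run(self):
        eth = np.zeros(100, dtype=bool)
        eth[10:40] = True
        assert quantify_licks(eth, fps=30.0) == (1, 1.0)

    def test_gap_merging(self):
        eth = np.zeros(50, dtype=bool)
        eth[5:10] = True
        eth[12:15] = True  # gap of 2 frames
        assert quantify_licks(eth, fps=30.0, gap_frames=3)[0] == 1
        assert quantify_licks(eth, fps=30.0, gap_frames=2)[0] == 2
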