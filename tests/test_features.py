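"""Feature extraction: interpolation/smoothing, kinematic and geometric
features against hand-computed values, z-scoring, behavioral scores, and the
oracle equivalence between features and the generator's geometry truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fomopipe.features import (
    ArenaConfig,
    FeatureMatrix,
    KeypointTrack,
    NODE_NAMES,
    compute_features,
    freeze_dash_score,
    hotplate_scores,
    preprocess_keypoints,
    reward_seeking,
    trial_windows,
    zscore_features,
)


def _track_from_centers(centers: np.ndarray, phi: float = 0.0, fps: float = 30.0) -> KeypointTrack:
    """Build a rigid 9-node track translating along ``centers``."""
    u = np.array([np.cos(phi), np.sin(phi)])
    nvec = np.array([-u[1], u[0]])
    offsets = {
        "nose": 18 * u, "left_ear": 9 * u + 7 * nvec, "right_ear": 9 * u - 7 * nvec,
        "torso": 0 * u, "left_forepaw": 6 * u + 8 * nvec, "right_forepaw": 6 * u - 8 * nvec,
        "left_hindpaw": -10 * u + 9 * nvec, "right_hindpaw": -10 * u - 9 * nvec,
        "tail_base": -25 * u,
    }
    coords = np.stack([centers + offsets[n] for n in NODE_NAMES], axis=1)
    return KeypointTrack(coords=coords, fps=fps)


class TestPreprocess:
    def test_identity_without_missing(self):
        track = _track_from_centers(np.cumsum(np.ones((20, 2)), axis=0) + 50)
        out = preprocess_keypoints(track, window_frames=1)
        np.testing.assert_array_equal(out.coords, track.coords)

    def test_linear_midpoint(self):
        coords = np.tile(np.array([[10.0, 10.0]] * 9), (3, 1, 1))
        coords[0, 0] = [10.0, 10.0]
        coords[1, 0] = [np.nan, np.nan]
        coords[2, 0] = [12.0, 12.0]
        out = preprocess_keypoints(KeypointTrack(coords=coords), window_frames=1)
        np.testing.assert_allclose(out.coords[1, 0], [11.0, 11.0])

    def test_constant_track_unchanged_by_smoothing(self):
        coords = np.full((15, 9, 2), 42.0)
        out = preprocess_keypoints(KeypointTrack(coords=coords), window_frames=7)
        np.testing.assert_allclose(out.coords, 42.0)

    def test_all_missing_node_raises(self):
        coords = np.full((10, 9, 2), 5.0)
        coords[:, 2, :] = np.nan
        with pytest.raises(ValueError, match="right_ear"):
            preprocess_keypoints(KeypointTrack(coords=coords))


class TestKinematics:
    def test_straight_path_velocity_and_tortuosity(self):
        centers = np.stack([np.arange(60) * 10.0 + 50, np.full(60, 100.0)], axis=1)
        track = _track_from_centers(centers)
        arena = ArenaConfig(image_size=(2000, 480), zone_edges=(600, 1200), port_xy=(1900, 100))
        fm = compute_features(track, arena)
        np.testing.assert_allclose(fm.values["velocity"][1:], 300.0 * 10 / 10)
        assert np.allclose(fm.values["velocity"][1:], 300.0)
        np.testing.assert_allclose(fm.values["tortuosity_1s"][30:], 1.0, atol=1e-9)

    def test_right_angle_tortuosity_is_7_over_5(self):
        # two legs of 3 px then 4 px at a right angle inside a 2-frame window
        centers = np.array([[50.0, 50.0], [53.0, 50.0], [53.0, 54.0]])
        track = _track_from_centers(centers, fps=2.0)
        arena = ArenaConfig(image_size=(640, 480))
        fm = compute_features(track, arena)
        assert fm.values["tortuosity_1s"].iloc[2] == pytest.approx(7.0 / 5.0)

    def test_velocity_time_reversal(self, small_session):
        _, _, _, truth = small_session
        track = truth.clean_track
        arena = ArenaConfig()
        fm = compute_features(track, arena)
        from dataclasses import replace

        rev = replace(track, coords=track.coords[::-1].copy())
        fm_rev = compute_features(rev, arena)
        np.testing.assert_allclose(
            fm.values["velocity"].to_numpy()[1:],
            fm_rev.values["velocity"].to_numpy()[1:][::-1],
            rtol=1e-9,
        )

    def test_angle_to_port_zero_when_aligned(self):
        centers = np.tile(np.array([100.0, 240.0]), (5, 1))
        track = _track_from_centers(centers, phi=0.0)  # facing +x
        arena = ArenaConfig(port_xy=(480.0, 240.0))
        fm = compute_features(track, arena)
        np.testing.assert_allclose(fm.values["angle_to_port"], 0.0, atol=1e-9)
        assert (fm.values["oriented_to_port"] == 1).all()


class TestDiscreteAndInvariants:
    def test_zone_partition_and_range(self, small_session):
        cfg, _, _, truth = small_session
        fm = compute_features(truth.clean_track, cfg.arena)
        assert set(np.unique(fm.values["zone"])) <= {1, 2, 3}

    def test_tortuosity_at_least_one(self, small_session):
        cfg, _, _, truth = small_session
        fm = compute_features(truth.clean_track, cfg.arena)
        assert (fm.values["tortuosity_1s"] >= 1.0).all()
        assert (fm.values["tortuosity_5s"] >= 1.0).all()

    def test_oracle_equivalence_with_generator(self, small_session):
        """oriented_and_touching reproduces the planted geometry truth
        frame-for-frame on the clean track."""
        cfg, _, _, truth = small_session
        fm = compute_features(truth.clean_track, cfg.arena)
        oat = fm.values["oriented_and_touching"].to_numpy().astype(bool)
        np.testing.assert_array_equal(oat, truth.attending_frames)


class TestZscore:
    def test_standardizes_and_is_idempotent(self, small_session):
        cfg, _, _, truth = small_session
        fm = compute_features(truth.clean_track, cfg.arena)
        z = zscore_features(fm)
        for c in z.continuous_names:
            assert abs(z.values[c].mean()) < 1e-9
            assert abs(z.values[c].std(ddof=0) - 1) < 1e-9
        z2 = zscore_features(z)
        np.testing.assert_allclose(z2.values[z.continuous_names], z.values[z.continuous_names], atol=1e-12)
        # discrete columns untouched
        np.testing.assert_array_equal(z.values["zone"], fm.values["zone"])

    def test_zero_variance_column_raises(self):
        fm = FeatureMatrix(
            values=pd.DataFrame({"velocity": [1.0, 1.0, 1.0]}),
            kinds={"velocity": "continuous"},
        )
        with pytest.raises(ValueError, match="velocity"):
            zscore_features(fm)


class TestScores:
    def _fm(self, velocity, accel=None, dist=None):
        n = len(velocity)
        values = pd.DataFrame(
            {
                "velocity": velocity,
                "acceleration": accel if accel is not None else np.zeros(n),
                "dist_to_port": dist if dist is not None else np.zeros(n),
            }
        )
        kinds = {c: "continuous" for c in values.columns}
        return FeatureMatrix(values=values, kinds=kinds, fps=30.0)

    def test_all_zero_velocity_freezes(self):
        res = freeze_dash_score(self._fm(np.zeros(10)), v_thresh=1.0, a_thresh=1.0, dash_thresh=100.0)
        assert res["n_freeze"] == 10 and res["freeze"].all()

    def test_all_dash_gives_undefined_ratio(self):
        res = freeze_dash_score(self._fm(np.full(10, 500.0)), v_thresh=1.0, a_thresh=1.0, dash_thresh=100.0)
        assert res["n_freeze"] == 0 and np.isnan(res["ratio"])

    def test_handbuilt_freeze_count(self):
        v = np.array([0.5, 0.5, 5, 5, 0.5, 5, 0.5, 5, 5, 5])
        res = freeze_dash_score(self._fm(v), v_thresh=1.0, a_thresh=1.0, dash_thresh=100.0)
        assert res["n_freeze"] == 4

    def test_reward_seeking_extremes(self):
        assert reward_seeking(self._fm(np.zeros(10), dist=np.zeros(10)), dist_thresh=5.0) == 100.0
        assert reward_seeking(self._fm(np.zeros(10), dist=np.ones(10)), dist_thresh=0.0) == 0.0
        half = np.concatenate([np.zeros(5), np.ones(5) * 10])
        assert reward_seeking(self._fm(np.zeros(10), dist=half), dist_thresh=5.0) == 50.0

    @pytest.mark.parametrize(
        "paradigm,baseline,norm,diff",
        [(6.0, 3.0, 2.0, 3.0), (4.0, 4.0, 1.0, 0.0), (0.0, 3.0, 0.0, -3.0)],
    )
    def test_hotplate_scores(self, paradigm, baseline, norm, diff):
        n, d = hotplate_scores(paradigm, baseline)
        assert n == pytest.approx(norm) and d == pytest.approx(diff)

    def test_hotplate_zero_baseline(self):
        with pytest.warns(UserWarning):
            n, d = hotplate_scores(2.0, 0.0)
        assert np.isnan(n) and d == 2.0


class TestTrialWindows:
    def test_bins_partition_post_window(self):
        tw = trial_windows(np.array([10.0, 40.0]), fps=30.0, n_frames=3000)
        for i in range(2):
            assert tw.bins[i, 0, 0] == tw.baseline[i, 1]
            for b in range(2):
                assert tw.bins[i, b, 1] == tw.bins[i, b + 1, 0]
            assert tw.bins[i, -1, 1] - tw.bins[i, 0, 0] == 15 * 30

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError):
            trial_windows(np.array([1.0]), fps=30.0, n_frames=3000)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(min_value=-100, max_value=100), min_size=3, max_size=30))
def test_interpolation_preserves_observed_values(vals):
    """Linear interpolation never alters observed coordinates."""
    n = len(vals)
    coords = np.tile(np.array(vals, dtype=float)[:, None, None], (1, 9, 2)) + 200
    mask = np.zeros(n, dtype=bool)
    mask[1:-1:2] = True
    coords[mask, 0, 0] = np.nan
    out = preprocess_keypoints(KeypointTrack(coords=coords), window_frames=1)
    np.testing.assert_allclose(out.coords[~mask, 0, 0], np.array(vals)[~mask] + 200)
    assert not np.isnan(out.coords).any()
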