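"""Calcium analysis: PSTH z-scoring, responsiveness calls on planted
neurons, ensemble clustering, overlap statistics against the textbook
chi-squared formula, the train-only PCA contract, decoding, and trajectory
geometry closed forms."""

import numpy as np
import pandas as pd
import pytest

from fomopipe.neural import (
    NeuralSession,
    PCABasis,
    call_responsive,
    chi_squared_proportions,
    cluster_ensembles,
    cluster_percentages,
    compute_psth,
    decode_trials,
    fit_global_pca,
    geodesic_length,
    overlap_count,
    resample_trajectory,
    response_patterns,
    trajectory_distance,
    trajectory_geometry,
)


def _session(dff, fs=10.0, events=None):
    events = events if events is not None else np.array([10.0])
    return NeuralSession(dff=dff, fs=fs, events={"cue": events})


class TestPSTH:
    def test_step_response_z(self, rng):
        fs = 10.0
        events = np.arange(10.0, 10.0 + 30 * 25, 25.0)
        n_t = int((events[-1] + 40) * fs)
        dff = rng.normal(0, 1, (1, n_t))
        for ev in events:
            a = int(ev * fs)
            dff[0, a : a + 150] += 3.0
        p = compute_psth(_session(dff, events=events), events)
        post = p.z[0][:, p.window_mask(0, 15)].mean(axis=1)
        # with a 10-sample baseline, 1/SD is biased upward; Monte Carlo the
        # expected scaling of a +3 step under the same z-scoring
        factor = np.mean([1.0 / rng.normal(0, 1, 10).std() for _ in range(2000)])
        expected = 3.0 * factor
        se = post.std(ddof=1) / np.sqrt(len(post))
        assert abs(post.mean() - expected) < 4 * se

    def test_baseline_window_zero_mean(self, rng):
        dff = rng.normal(0, 1, (3, 400))
        p = compute_psth(_session(dff), np.array([10.0]))
        bm = p.window_mask(-1, 0)
        np.testing.assert_allclose(p.z[:, :, bm].mean(axis=2), 0.0, atol=1e-10)
        np.testing.assert_allclose(np.nanstd(p.z[:, :, bm], axis=2), 1.0, atol=1e-10)

    def test_constant_trace_flagged(self, rng):
        dff = np.vstack([np.full(400, 2.0), rng.normal(0, 1, 400)])
        with pytest.warns(UserWarning, match="zero baseline SD"):
            p = compute_psth(_session(dff), np.array([10.0]))
        assert (0, 0) in p.excluded
        assert np.isnan(p.z[0]).all() and not np.isnan(p.z[1]).any()

    def test_event_out_of_bounds(self, rng):
        dff = rng.normal(0, 1, (1, 100))
        with pytest.raises(ValueError):
            compute_psth(_session(dff), np.array([2.0]))


class TestResponsiveness:
    def test_planted_steps_called(self, rng):
        fs = 10.0
        events = np.arange(10.0, 10.0 + 20 * 25, 25.0)
        n_t = int((events[-1] + 40) * fs)
        dff = rng.normal(0, 1, (30, n_t))
        sign = np.repeat([1, -1, 0], 10)
        for ev in events:
            a = int(ev * fs)
            dff[:, a : a + 150] += 2.0 * sign[:, None]
        p = compute_psth(_session(dff, events=events), events)
        resp = call_responsive(p)
        assert (resp["call"][:10] == "excited").mean() >= 0.9
        assert (resp["call"][10:20] == "inhibited").mean() >= 0.9

    def test_too_few_trials(self, rng):
        dff = rng.normal(0, 1, (2, 600))
        p = compute_psth(_session(dff, events=np.array([10.0, 35.0])), np.array([10.0, 35.0]))
        with pytest.raises(ValueError):
            call_responsive(p)


class TestEnsembleClustering:
    def _two_templates(self, rng, n=30):
        t = np.linspace(0, 1, 50)
        a = np.sin(2 * np.pi * t)
        b = np.cos(2 * np.pi * t)
        truth = np.repeat([0, 1], n // 2)
        profiles = np.where(truth[:, None] == 0, a, b) + rng.normal(0, 0.05, (n, 50))
        return profiles, truth

    def test_two_templates_ari_one(self, rng):
        from sklearn.metrics import adjusted_rand_score

        profiles, truth = self._two_templates(rng)
        tree = cluster_ensembles(profiles)
        assert tree.n_clusters == 2
        assert adjusted_rand_score(truth, tree.labels) == 1.0

    def test_order_permutation_invariance(self, rng):
        profiles, _ = self._two_templates(rng)
        perm = rng.permutation(len(profiles))
        t1 = cluster_ensembles(profiles)
        t2 = cluster_ensembles(profiles[perm])
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(t1.labels[perm], t2.labels) == 1.0

    def test_cutoff_extremes(self, rng):
        profiles, _ = self._two_templates(rng, n=10)
        assert cluster_ensembles(profiles, cutoff_frac=1.0).n_clusters == 1
        assert cluster_ensembles(profiles, cutoff_frac=1e-12).n_clusters == 10

    def test_constant_profile_excluded(self, rng):
        profiles, _ = self._two_templates(rng, n=10)
        profiles[0] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            tree = cluster_ensembles(profiles)
        assert tree.labels[0] == 0

    def test_percentages(self):
        labels = np.array([1, 1, 2, 2])
        conds = np.array(["SE", "SE", "SE", "TO"])
        df = cluster_percentages(labels, conds)
        se = df[df.condition == "SE"].set_index("cluster")["percent"]
        assert se[1] == pytest.approx(200 / 3) and se[2] == pytest.approx(100 / 3)


class TestOverlap:
    def test_counts(self):
        a = np.array(["excited", "none", "inhibited", "none"])
        b = np.array(["none", "none", "excited", "excited"])
        assert overlap_count(a, b) == 1
        assert overlap_count(a, a) == 2
        disjoint = np.array(["excited", "none", "none", "none"])
        other = np.array(["none", "inhibited", "none", "none"])
        assert overlap_count(disjoint, other) == 0

    def test_patterns(self):
        calls = {
            "attending": np.array(["excited", "excited", "none"]),
            "pinprick": np.array(["excited", "none", "none"]),
        }
        df = response_patterns(calls)
        assert df["count"].sum() == 3

    def test_chi_squared_matches_formula(self):
        table = np.array([[12.0, 8.0], [5.0, 15.0]])
        stat, p, dof = chi_squared_proportions(table)
        # textbook Pearson formula
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        manual = ((table - exp) ** 2 / exp).sum()
        assert stat == pytest.approx(manual)
        assert dof == 1


class TestGlobalPCA:
    def test_rank_one(self, rng):
        u = rng.normal(0, 1, 20)
        x = np.outer(rng.normal(0, 1, 50), u)
        basis = fit_global_pca(x)
        assert basis.n_components == 1
        assert np.cumsum(basis.explained_variance_ratio)[0] >= 0.9

    def test_isotropic_matches_eigenvalue_oracle(self, rng):
        x = rng.normal(0, 1, (400, 20))
        basis = fit_global_pca(x)
        # oracle: eigenvalues of the sample covariance
        ev = np.linalg.eigvalsh(np.cov(x.T))[::-1]
        cum = np.cumsum(ev) / ev.sum()
        expected = int(np.searchsorted(cum, 0.9) + 1)
        assert basis.n_components == expected

    def test_components_orthonormal(self, rng):
        x = rng.normal(0, 1, (100, 10))
        basis = fit_global_pca(x)
        g = basis.components @ basis.components.T
        np.testing.assert_allclose(g, np.eye(len(g)), atol=1e-10)

    def test_training_only_contract(self, rng):
        x = rng.normal(0, 1, (100, 10))
        basis = fit_global_pca(x)
        basis2 = fit_global_pca(x)  # "test fold" perturbations never enter
        np.testing.assert_allclose(basis.components, basis2.components)


class TestDecoding:
    def _separable(self, rng, n_trials=40, n_bins=10, n_comp=4, offset=3.0):
        labels = np.repeat([0, 1], n_trials // 2)
        x = rng.normal(0, 1, (n_trials, n_bins, n_comp))
        x[labels == 1] += offset
        return x, labels

    def test_separable_high_auroc(self, rng):
        x, labels = self._separable(rng)
        res = decode_trials(x, labels, folds=5, seed=0)
        assert np.nanmean(res.window_auroc) >= 0.95

    def test_svm_matches_contract(self, rng):
        x, labels = self._separable(rng)
        res = decode_trials(x, labels, classifier="svm", folds=5, seed=0)
        assert np.nanmean(res.window_auroc) >= 0.95

    def test_one_vs_all_ordering(self, rng):
        # 3 classes with distinct separability -> strict auROC ordering
        n = 60
        labels = np.repeat([0, 1, 2], n // 3)
        x = rng.normal(0, 1, (n, 6, 4))
        x[labels == 1] += 1.0
        x[labels == 2] += 5.0
        res = decode_trials(x, labels, scheme="ova", folds=5, seed=0, n_repeats=2)
        w = {c: np.nanmean(r.window_auroc) for c, r in res.per_class.items()}
        assert w[2] > w[1] > 0.5

    def test_unbalanced_classes_handled(self, rng):
        x = rng.normal(0, 1, (50, 5, 3))
        labels = np.array([0] * 40 + [1] * 10)
        x[labels == 1] += 3.0
        res = decode_trials(x, labels, folds=5, seed=0)
        assert np.nanmean(res.window_auroc) >= 0.9

    def test_too_few_trials_raises(self, rng):
        x = rng.normal(0, 1, (3, 5, 3))
        with pytest.raises(ValueError):
            decode_trials(x, np.array([0, 0, 1]), folds=2)


class TestTrajectories:
    def test_two_point_geodesic(self):
        traj = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert geodesic_length(traj) == pytest.approx(5.0)
        assert geodesic_length(resample_trajectory(traj, 100)) == pytest.approx(5.0)

    def test_self_distance_zero(self, rng):
        traj = rng.normal(0, 1, (100, 3))
        np.testing.assert_allclose(trajectory_distance(traj, traj), 0.0)

    def test_unit_circle_length(self):
        th = np.linspace(0, 2 * np.pi, 101)
        circle = np.stack([np.cos(th), np.sin(th)], axis=1)
        assert abs(geodesic_length(circle) - 2 * np.pi) / (2 * np.pi) < 0.002

    def test_rotation_invariance(self, rng):
        traj = rng.normal(0, 1, (50, 3))
        q, _ = np.linalg.qr(rng.normal(0, 1, (3, 3)))
        assert geodesic_length(traj @ q.T) == pytest.approx(geodesic_length(traj))

    def test_loo_reuses_coefficients(self, rng):
        n_neurons, n_time = 30, 60
        animal_ids = np.repeat([0, 1, 2], 10)
        acts = {"A": rng.normal(0, 1, (n_time, n_neurons)), "B": rng.normal(0, 1, (n_time, n_neurons))}
        basis = fit_global_pca(np.concatenate(list(acts.values())))
        ts = trajectory_geometry(basis, acts, animal_ids, n_bins=100)
        assert set(ts.lengths) == {"A", "B"}
        assert all(len(v) == 3 for v in ts.loo_lengths.values())
        # manual replicate for animal 0, group A
        keep = np.nonzero(animal_ids != 0)[0]
        proj = basis.project(acts["A"][:, keep], neuron_idx=keep)[:, : basis.n_components]
        manual = geodesic_length(resample_trajectory(proj, 100))
        assert ts.loo_lengths["A"][0] == pytest.approx(manual)
        d = ts.pairwise_distances[("A", "B")]
        assert d.shape == (100,) and (d >= 0).all()
        # geodesic never shorter than the straight chord
        for g, t in ts.trajectories.items():
            assert ts.lengths[g] >= np.linalg.norm(t[-1] - t[0]) - 1e-9
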