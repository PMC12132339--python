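"""Cellular-resolution calcium analysis: peri-event z-scored responses,
responsiveness calls, hierarchical ensemble clustering, population decoding,
and neural-trajectory geometry.

The peri-stimulus window is [-5, +15] s around cue onset at 10 Hz, with
per-neuron-per-trial z-scoring against the [-1, 0) s baseline:
z(t) = (F(t) - Fm) / SD with Fm, SD the baseline mean and SD of dF/F0.
Responsiveness uses a paired Wilcoxon signed-rank test of 5-s baseline vs
5-s event window means across trials, with the excited/inhibited sign taken
from the mean z over the 0-15 s response window.

Population decoding follows a train-set-only PCA contract: the basis is fit
on trial-averaged activity of the training folds only, single trials are
projected with those fixed coefficients, and a GLM (L2 logistic regression)
or linear SVM is trained per timepoint, yielding an ROC curve as a function
of time plus a label-shuffled control.  Trajectory geometry resamples
trial-averaged component-space trajectories to 100 bins; geodesic length is
the summed distance between adjacent bins, and between-trajectory distance
is computed bin-by-bin, with leave-one-animal-out replicates reusing the
same PCA coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


@dataclass
class NeuralSession:
    """dF/F0 neurons x time matrix with events and co-registration ids."""

    dff: np.ndarray
    fs: float
    events: dict[str, np.ndarray]
    animal_id: str = ""
    coreg_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 2:
            raise ValueError("dff must be neurons x time")
        if self.coreg_ids is not None and len(np.unique(self.coreg_ids)) != len(self.coreg_ids):
            raise ValueError("coreg_ids must be unique within a session")

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]


@dataclass
class PSTH:
    """Peri-event z-scored responses: neurons x trials x timebins."""

    z: np.ndarray
    t: np.ndarray  # bin times relative to event onset (s)
    fs: float
    baseline_window: tuple[float, float]
    excluded: list[tuple[int, int]] = field(default_factory=list)  # (neuron, trial) with SD=0

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask over timebins for [lo, hi) seconds."""
        return (self.t >= lo) & (self.t < hi)


def compute_psth(
    sess: NeuralSession,
    events_s: np.ndarray,
    pre_s: float = 5.0,
    post_s: float = 15.0,
    baseline: tuple[float, float] = (-1.0, 0.0),
) -> PSTH:
    """Event-aligned z-scores with per-neuron-per-trial baseline normalization.

    Neuron-trial pairs whose baseline SD is zero are flagged, excluded
    (NaN), and reported in ``PSTH.excluded``.
    """
    fs = sess.fs
    events_s = np.asarray(events_s, dtype=float)
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    t = np.arange(-n_pre, n_post) / fs
    bmask = (t >= baseline[0]) & (t < baseline[1])
    n_neurons = sess.n_neurons
    n_trials = len(events_s)
    z = np.full((n_neurons, n_trials, n_pre + n_post), np.nan)
    excluded: list[tuple[int, int]] = []
    for j, ev in enumerate(events_s):
        a = int(round(ev * fs)) - n_pre
        b = a + n_pre + n_post
        if a < 0 or b > sess.dff.shape[1]:
            raise ValueError(f"event at {ev:.2f}s exceeds recording bounds")
        seg = sess.dff[:, a:b]
        fm = seg[:, bmask].mean(axis=1)
        sd = seg[:, bmask].std(axis=1, ddof=0)
        bad = sd == 0
        for i in np.nonzero(bad)[0]:
            excluded.append((int(i), int(j)))
        with np.errstate(invalid="ignore", divide="ignore"):
            zz = (seg - fm[:, None]) / sd[:, None]
        zz[bad] = np.nan
        z[:, j, :] = zz
    if excluded:
        warnings.warn(f"{len(excluded)} neuron-trial pairs had zero baseline SD; excluded")
    return PSTH(z=z, t=t, fs=fs, baseline_window=baseline, excluded=excluded)


def call_responsive(
    psth: PSTH,
    alpha: float = 0.05,
    base_window: tuple[float, float] = (-5.0, 0.0),
    event_window: tuple[float, float] = (0.0, 5.0),
    sign_window: tuple[float, float] = (0.0, 15.0),
) -> pd.DataFrame:
    """Per-neuron responsiveness by paired Wilcoxon signed-rank test.

    Per-trial mean z over the 5-s baseline window is compared with the 5-s
    event window; significant neurons are called excited or inhibited by the
    sign of their mean z over the 0-15 s response window.

    Returns a DataFrame with columns neuron, p, call, mean_z.
    """
    if psth.z.shape[1] < 6:
        raise ValueError("need at least 6 trials for the signed-rank test")
    bm = psth.window_mask(*base_window)
    em = psth.window_mask(*event_window)
    sm = psth.window_mask(*sign_window)
    rows = []
    for i in range(psth.z.shape[0]):
        zi = psth.z[i]
        ok = ~np.isnan(zi).any(axis=1)
        base = zi[ok][:, bm].mean(axis=1)
        evt = zi[ok][:, em].mean(axis=1)
        mean_z = float(np.nanmean(zi[ok][:, sm])) if ok.any() else np.nan
        if ok.sum() < 6 or np.allclose(base, evt):
            p = 1.0
        else:
            p = float(stats.wilcoxon(base, evt).pvalue)
        if p < alpha:
            call = "excited" if mean_z > 0 else "inhibited"
        else:
            call = "none"
        rows.append({"neuron": i, "p": p, "call": call, "mean_z": mean_z})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hierarchical ensemble clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterTree:
    """Ward-on-correlation-distance hierarchy cut at 30% of max linkage."""

    linkage: np.ndarray
    labels: np.ndarray  # per input neuron; 0 = excluded (constant profile)
    cutoff: float
    kept: np.ndarray  # indices of clustered neurons

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels[self.labels > 0]))


def cluster_ensembles(profiles: np.ndarray, cutoff_frac: float = 0.3) -> ClusterTree:
    """Cluster neurons by their concatenated mean response profiles.

    Linkage is Ward's method on correlation distance (1 - Pearson r between
    profiles); flat clusters are cut at ``cutoff_frac`` of the maximum
    linkage height.  Constant profiles (undefined correlation) are excluded
    with a warning and labeled 0.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 neurons")
    sd = profiles.std(axis=1, ddof=0)
    kept = np.nonzero(sd > 0)[0]
    if len(kept) < profiles.shape[0]:
        warnings.warn(f"{profiles.shape[0] - len(kept)} constant profiles excluded from clustering")
    if len(kept) < 2:
        raise ValueError("fewer than 2 non-constant profiles")
    d = pdist(profiles[kept], metric="correlation")
    z = linkage(d, method="ward")
    cutoff = cutoff_frac * z[:, 2].max()
    flat = fcluster(z, t=cutoff, criterion="distance")
    labels = np.zeros(profiles.shape[0], dtype=int)
    labels[kept] = flat
    return ClusterTree(linkage=z, labels=labels, cutoff=float(cutoff), kept=kept)


def cluster_percentages(labels: np.ndarray, conditions: np.ndarray) -> pd.DataFrame:
    """Percent of each condition's neurons falling in each cluster."""
    labels = np.asarray(labels)
    conditions = np.asarray(conditions)
    rows = []
    for cond in np.unique(conditions):
        m = conditions == cond
        denom = max(int(m.sum()), 1)
        for c in np.unique(labels[labels > 0]):
            rows.append(
                {"condition": cond, "cluster": int(c), "percent": 100.0 * (labels[m] == c).sum() / denom}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# overlap statistics
# ---------------------------------------------------------------------------

def response_patterns(calls_by_event: dict[str, np.ndarray]) -> pd.DataFrame:
    """Counts of joint excitation/inhibition patterns across event types
    (the dendrogram-table view), for co-registered neurons."""
    events = list(calls_by_event)
    arrays = [np.asarray(calls_by_event[e]) for e in events]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("call arrays must cover the same co-registered neurons")
    df = pd.DataFrame({e: a for e, a in zip(events, arrays)})
    out = df.value_counts().reset_index(name="count")
    return out.sort_values("count", ascending=False).reset_index(drop=True)


def overlap_count(calls_a: np.ndarray, calls_b: np.ndarray) -> int:
    """Neurons responsive (excited or inhibited) to both event types."""
    a = np.asarray(calls_a) != "none"
    b = np.asarray(calls_b) != "none"
    if len(a) != len(b):
        raise ValueError("call arrays must have equal length")
    return int((a & b).sum())


def chi_squared_proportions(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-squared test (no continuity correction) on a contingency
    table of responsiveness proportions across conditions."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("contingency table has empty margins; test validity limited")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


# ---------------------------------------------------------------------------
# train-set-only PCA and decoding
# ---------------------------------------------------------------------------

@dataclass
class PCABasis:
    """Global PCA basis with the 90%-variance component count."""

    components: np.ndarray  # (n_components, n_neurons)
    mean: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components: int

    def project(self, x: np.ndarray, neuron_idx: np.ndarray | None = None) -> np.ndarray:
        """Project samples x neurons onto the basis; with ``neuron_idx`` only
        those neurons' coefficients are used (the LOO contract: coefficients
        fixed, neurons included vary)."""
        x = np.asarray(x, dtype=float)
        if neuron_idx is None:
            return (x - self.mean) @ self.components.T
        idx = np.asarray(neuron_idx)
        return (x - self.mean[idx]) @ self.components[:, idx].T


def fit_global_pca(train_averages: np.ndarray, var_threshold: float = 0.90) -> PCABasis:
    """PCA on training-fold trial averages only (samples x neurons); keeps
    the smallest component count reaching ``var_threshold`` cumulative
    explained variance."""
    x = np.asarray(train_averages, dtype=float)
    pca = PCA(svd_solver="full")
    pca.fit(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, var_threshold) + 1)
    n_comp = min(n_comp, len(cum))
    return PCABasis(
        components=pca.components_.copy(),
        mean=pca.mean_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        n_components=n_comp,
    )


@dataclass
class DecodingResult:
    """Per-timepoint and window-averaged auROC with shuffled control."""

    auroc_time: np.ndarray  # (bins,) mean over folds
    auroc_time_folds: np.ndarray  # (folds, bins)
    window_auroc: np.ndarray  # (folds,)
    shuffled_auroc_time: np.ndarray
    shuffled_window_auroc: np.ndarray
    classifier: str
    scheme: str
    folds: int
    per_class: dict[object, "DecodingResult"] = field(default_factory=dict)


def _make_classifier(kind: str, seed: int):
    if kind == "glm":
        return LogisticRegression(C=1.0, max_iter=1000, random_state=seed)  # L2 by default
    if kind == "svm":
        return SVC(kernel="linear", C=1.0, random_state=seed)
    raise ValueError(f"unknown classifier '{kind}'")


def _binary_decode(
    x: np.ndarray, y: np.ndarray, classifier: str, folds: int, seed: int, window: tuple[int, int], shuffle_train: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Per-fold per-timepoint auROC; returns (folds x bins aurocs, window means)."""
    n_trials, n_bins, _ = x.shape
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    aurocs = np.full((folds, n_bins), np.nan)
    for f, (tr, te) in enumerate(skf.split(np.zeros(n_trials), y)):
        y_tr = y[tr].copy()
        # balanced training: subsample the majority class
        classes, counts = np.unique(y_tr, return_counts=True)
        n_min = counts.min()
        keep = np.concatenate(
            [rng.choice(np.nonzero(y_tr == c)[0], size=n_min, replace=False) for c in classes]
        )
        keep.sort()
        tr_bal = tr[keep]
        y_bal = y[tr_bal].copy()
        if shuffle_train:
            rng.shuffle(y_bal)
        for b in range(n_bins):
            clf = _make_classifier(classifier, seed)
            try:
                clf.fit(x[tr_bal, b, :], y_bal)
                scores = clf.decision_function(x[te, b, :])
                aurocs[f, b] = roc_auc_score(y[te], scores)
            except ValueError:  # single-class shuffle draw
                aurocs[f, b] = 0.5
    w0, w1 = window
    return aurocs, np.nanmean(aurocs[:, w0:w1], axis=1)


def decode_trials(
    x: np.ndarray,
    labels: np.ndarray,
    scheme: str = "binary",
    classifier: str = "glm",
    folds: int = 5,
    seed: int = 0,
    window_bins: tuple[int, int] | None = None,
    n_repeats: int = 3,
) -> DecodingResult:
    """Cross-validated population decoding with per-timepoint ROC.

    Parameters
    ----------
    x : (trials, timebins, components) projected single-trial activity.
    labels : per-trial class labels (2 classes for ``scheme='binary'``).
    scheme : 'binary', or 'ova' (one-vs-all: each class against a
        trial-matched subsample of the rest, repeated ``n_repeats`` times
        with fresh subsamples).
    window_bins : [start, stop) bin range for the window-averaged auROC
        (defaults to all bins).

    A classifier is trained per timepoint on a class-balanced subsample of
    each training fold; auROC is computed on held-out trials from the
    continuous decision value.  The shuffled control repeats the process
    with training labels permuted, same folds.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if x.ndim != 3:
        raise ValueError("x must be (trials, timebins, components)")
    window = window_bins if window_bins is not None else (0, x.shape[1])
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 trials")

    if scheme == "binary":
        if len(classes) != 2:
            raise ValueError("binary scheme requires exactly 2 classes")
        y = (labels == classes[1]).astype(int)
        a, w = _binary_decode(x, y, classifier, folds, seed, window, shuffle_train=False)
        sa, sw = _binary_decode(x, y, classifier, folds, seed, window, shuffle_train=True)
        return DecodingResult(
            auroc_time=np.nanmean(a, axis=0),
            auroc_time_folds=a,
            window_auroc=w,
            shuffled_auroc_time=np.nanmean(sa, axis=0),
            shuffled_window_auroc=sw,
            classifier=classifier,
            scheme=scheme,
            folds=folds,
        )
    if scheme != "ova":
        raise ValueError(f"unknown scheme '{scheme}'")

    rng = np.random.default_rng(seed)
    per_class: dict[object, DecodingResult] = {}
    for c in classes:
        pos = np.nonzero(labels == c)[0]
        others = np.nonzero(labels != c)[0]
        reps = []
        for r in range(n_repeats):
            neg = rng.choice(others, size=min(len(pos), len(others)), replace=False)
            idx = np.concatenate([pos, neg])
            y = (labels[idx] == c).astype(int)
            a, w = _binary_decode(x[idx], y, classifier, folds, seed + r, window, shuffle_train=False)
            sa, sw = _binary_decode(x[idx], y, classifier, folds, seed + r, window, shuffle_train=True)
            reps.append((a, w, sa, sw))
        a = np.nanmean([r[0] for r in reps], axis=0)
        sa = np.nanmean([r[2] for r in reps], axis=0)
        per_class[c] = DecodingResult(
            auroc_time=np.nanmean(a, axis=0),
            auroc_time_folds=a,
            window_auroc=np.nanmean([r[1] for r in reps], axis=0),
            shuffled_auroc_time=np.nanmean(sa, axis=0),
            shuffled_window_auroc=np.nanmean([r[3] for r in reps], axis=0),
            classifier=classifier,
            scheme="ova",
            folds=folds,
        )
    mean_time = np.nanmean([r.auroc_time for r in per_class.values()], axis=0)
    mean_folds = np.nanmean([r.auroc_time_folds for r in per_class.values()], axis=0)
    return DecodingResult(
        auroc_time=mean_time,
        auroc_time_folds=mean_folds,
        window_auroc=np.nanmean([r.window_auroc for r in per_class.values()], axis=0),
        shuffled_auroc_time=np.nanmean([r.shuffled_auroc_time for r in per_class.values()], axis=0),
        shuffled_window_auroc=np.nanmean([r.shuffled_window_auroc for r in per_class.values()], axis=0),
        classifier=classifier,
        scheme="ova",
        folds=folds,
        per_class=per_class,
    )


# ---------------------------------------------------------------------------
# trajectory geometry
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySet:
    """Component-space trajectories with geodesic lengths, pairwise bin-wise
    distances, and leave-one-animal-out replicates."""

    trajectories: dict[str, np.ndarray]  # group -> (bins, components)
    lengths: dict[str, float]
    pairwise_distances: dict[tuple[str, str], np.ndarray]  # (bins,)
    loo_lengths: dict[str, np.ndarray]
    loo_pairwise: dict[tuple[str, str], np.ndarray]  # (iterations, bins)
    n_bins: int


def resample_trajectory(traj: np.ndarray, n_bins: int = 100) -> np.ndarray:
    """Linear resampling of a (time, components) trajectory to n_bins."""
    traj = np.asarray(traj, dtype=float)
    if traj.shape[0] == n_bins:
        return traj
    src = np.linspace(0.0, 1.0, traj.shape[0])
    dst = np.linspace(0.0, 1.0, n_bins)
    return np.stack([np.interp(dst, src, traj[:, c]) for c in range(traj.shape[1])], axis=1)


def geodesic_length(traj: np.ndarray) -> float:
    """Sum of Euclidean distances between adjacent bins."""
    traj = np.asarray(traj, dtype=float)
    return float(np.linalg.norm(np.diff(traj, axis=0), axis=1).sum())


def trajectory_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Bin-by-bin Euclidean distance between two trajectories."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("trajectories must share shape")
    return np.linalg.norm(a - b, axis=1)


def trajectory_geometry(
    basis: PCABasis,
    group_activity: dict[str, np.ndarray],
    animal_ids: np.ndarray,
    n_bins: int = 100,
) -> TrajectorySet:
    """Trajectory metrics in the 90%-variance subspace with LOO replicates.

    ``group_activity`` maps each group to its trial-averaged (time, neurons)
    activity; all groups share the neuron ordering of the basis.
    Leave-one-animal-out drops all of one animal's neurons per iteration
    while reusing the same PCA coefficients; groups represented by a single
    animal are flagged as degenerate.
    """
    animal_ids = np.asarray(animal_ids)
    nc = basis.n_components
    trajs = {
        g: resample_trajectory(basis.project(act)[:, :nc], n_bins) for g, act in group_activity.items()
    }
    lengths = {g: geodesic_length(t) for g, t in trajs.items()}
    pairs = {
        (g1, g2): trajectory_distance(trajs[g1], trajs[g2])
        for g1, g2 in combinations(sorted(trajs), 2)
    }
    animals = np.unique(animal_ids)
    if len(animals) < 2:
        warnings.warn("single animal: leave-one-animal-out is degenerate")
    loo_trajs: dict[str, list[np.ndarray]] = {g: [] for g in trajs}
    for a in animals:
        keep = np.nonzero(animal_ids != a)[0]
        for g, act in group_activity.items():
            proj = basis.project(act[:, keep], neuron_idx=keep)[:, :nc]
            loo_trajs[g].append(resample_trajectory(proj, n_bins))
    loo_lengths = {g: np.array([geodesic_length(t) for t in ts]) for g, ts in loo_trajs.items()}
    loo_pairwise = {
        (g1, g2): np.stack(
            [trajectory_distance(loo_trajs[g1][i], loo_trajs[g2][i]) for i in range(len(animals))]
        )
        for g1, g2 in pairs
    }
    return TrajectorySet(
        trajectories=trajs,
        lengths=lengths,
        pairwise_distances=pairs,
        loo_lengths=loo_lengths,
        loo_pairwise=loo_pairwise,
        n_bins=n_bins,
    )
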