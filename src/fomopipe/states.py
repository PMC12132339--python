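"""Unsupervised behavioral structure: low-dimensional embedding with density
clustering, and hidden-Markov consolidation of syllables + features into a
small set of behavioral states.

Two complementary routes to the same question ("is there a discrete
Attending state?"):

* :func:`embed_and_cluster` embeds the post-cue behavioral feature frames
  with UMAP and clusters the embedding with DBSCAN; clusters are annotated
  attending / not-attending (manually in the original workflow; a heuristic
  auto-annotation is provided for synthetic data).
* :func:`fit_hmm` / :func:`select_states` fit Gaussian-emission HMMs over
  concatenated one-hot syllable indicators and continuous features, scanning
  the number of hidden states (2-12 by default) and selecting by BIC (raw
  train log-likelihood is monotone in K, so it cannot select on its own;
  held-out likelihood is available as an alternative criterion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GaussianHMM
from sklearn.cluster import DBSCAN

from fomopipe.features import FeatureMatrix, HMM_FEATURE_SUBSET, TrialWindowSet


# ---------------------------------------------------------------------------
# embedding + density clustering
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingResult:
    """2-D embedding of behavioral frames with density-cluster labels."""

    points: np.ndarray  # (frames, 2)
    cluster_ids: np.ndarray  # -1 = noise
    frame_index: np.ndarray  # original frame index of each embedded row
    seed: int
    annotations: dict[int, str] = field(default_factory=dict)

    @property
    def clusters(self) -> np.ndarray:
        return np.unique(self.cluster_ids[self.cluster_ids >= 0])


def embed_and_cluster(
    fm: FeatureMatrix,
    windows: TrialWindowSet | None = None,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    eps: float = 0.5,
    min_samples: int = 10,
    columns: list[str] | None = None,
) -> EmbeddingResult:
    """UMAP embedding + DBSCAN clustering of (post-cue) feature frames.

    Frames are restricted to the 0-15 s post-onset windows when ``windows``
    is given.  Deterministic for a fixed seed (UMAP ``random_state``).
    """
    import umap  # deferred: slow import

    cols = columns or list(fm.values.columns)
    x = fm.values[cols].to_numpy(dtype=float)
    if windows is not None:
        mask = windows.post_mask(len(x))
        frame_index = np.nonzero(mask)[0]
        x = x[mask]
    else:
        frame_index = np.arange(len(x))
    if len(x) < min_samples:
        raise ValueError("fewer frames than min_samples")
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about forced single-threading
        points = reducer.fit_transform(x)
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(points)
    return EmbeddingResult(points=points, cluster_ids=labels, frame_index=frame_index, seed=seed)


def annotate_clusters(
    er: EmbeddingResult,
    fm: FeatureMatrix,
    column: str = "oriented_and_touching",
    threshold: float = 0.5,
) -> dict[int, str]:
    """Heuristic auto-annotation replacing the manual video-review step:
    clusters whose mean ``column`` value exceeds ``threshold`` are labeled
    attending.  Stores and returns the annotation map."""
    vals = fm.values[column].to_numpy(dtype=float)[er.frame_index]
    ann = {}
    for c in er.clusters:
        ann[int(c)] = "attending" if vals[er.cluster_ids == c].mean() > threshold else "not_attending"
    er.annotations = ann
    return ann


def overlay_on_embedding(er: EmbeddingResult, flags: np.ndarray) -> dict[int, float]:
    """Percent of each cluster's frames carrying an external flag (e.g.
    detector-classified attending frames mapped onto the embedding)."""
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(er.cluster_ids):
        raise ValueError("flags length must match embedded frames")
    return {int(c): 100.0 * flags[er.cluster_ids == c].mean() for c in er.clusters}


def condition_contrast(
    er: EmbeddingResult,
    flags_a: np.ndarray,
    flags_b: np.ndarray,
) -> dict[int, float]:
    """Per-cluster percentage-point difference between two conditions:
    (% of condition-A frames in cluster) - (% of condition-B frames)."""
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if len(a) != len(er.cluster_ids) or len(b) != len(er.cluster_ids):
        raise ValueError("flags length must match embedded frames")
    out = {}
    for c in er.clusters:
        m = er.cluster_ids == c
        pa = 100.0 * m[a].sum() / max(a.sum(), 1)
        pb = 100.0 * m[b].sum() / max(b.sum(), 1)
        out[int(c)] = pa - pb
    return out


# ---------------------------------------------------------------------------
# HMM over syllables + features
# ---------------------------------------------------------------------------

def build_observations(
    syllables: np.ndarray,
    fm: FeatureMatrix,
    feature_subset: tuple[str, ...] = HMM_FEATURE_SUBSET,
    alphabet: int | None = None,
) -> np.ndarray:
    """Concatenate one-hot syllable indicators with feature columns."""
    syllables = np.asarray(syllables, dtype=int)
    feats = fm.values[list(feature_subset)].to_numpy(dtype=float)
    if len(syllables) != len(feats):
        raise ValueError("syllables and features have different frame counts")
    a = alphabet if alphabet is not None else int(syllables.max()) + 1
    onehot = np.zeros((len(syllables), a))
    onehot[np.arange(len(syllables)), syllables] = 1.0
    return np.concatenate([onehot, feats], axis=1)


class _FullHistoryMonitor(ConvergenceMonitor):
    """Convergence monitor that records the whole log-likelihood trace."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: list[float] = []

    def report(self, log_prob: float) -> None:
        self.full_history.append(float(log_prob))
        super().report(log_prob)


class _RegularizedGaussianHMM(GaussianHMM):
    """GaussianHMM with a diagonal ridge on the covariances after each
    M-step, so near-degenerate emissions (e.g. one-hot blocks) stay
    invertible."""

    def __init__(self, *args, reg_covar: float = 1e-6, **kwargs):
        super().__init__(*args, **kwargs)
        self.reg_covar = reg_covar

    def _do_mstep(self, stats):
        super()._do_mstep(stats)
        if self.reg_covar > 0:
            if self.covariance_type == "full":
                self._covars_ += self.reg_covar * np.eye(self._covars_.shape[-1])[None]
            elif self.covariance_type == "diag":
                self._covars_ += self.reg_covar


@dataclass
class StateModel:
    """Fitted Gaussian-emission HMM with its selection record."""

    n_states: int
    startprob: np.ndarray
    transmat: np.ndarray
    means: np.ndarray
    covars: np.ndarray
    log_likelihood: float
    ll_history: list[float]
    bic: float
    selection_scores: dict[int, float] = field(default_factory=dict)
    criterion: str = "bic"
    _hmm: GaussianHMM | None = None

    def decode(self, obs: np.ndarray) -> np.ndarray:
        """Viterbi state sequence for an observation matrix."""
        if self._hmm is None:
            raise ValueError("model has no fitted backend")
        return self._hmm.predict(np.asarray(obs, dtype=float))


def fit_hmm(
    obs: np.ndarray,
    n_states: int,
    seed: int = 0,
    n_init: int = 5,
    covariance_type: str = "full",
    n_iter: int = 100,
    tol: float = 1e-4,
    reg_covar: float = 1e-6,
) -> StateModel:
    """EM-fit a Gaussian-emission HMM; best of ``n_init`` restarts by train
    log-likelihood.  The EM log-likelihood trace is recorded and is
    non-decreasing up to the tolerance.
    """
    obs = np.asarray(obs, dtype=float)
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    best = None
    for r in range(n_init):
        model = _RegularizedGaussianHMM(
            n_components=n_states,
            covariance_type=covariance_type,
            n_iter=n_iter,
            tol=tol,
            random_state=seed * 1000 + r,
            reg_covar=reg_covar,
        )
        model.monitor_ = _FullHistoryMonitor(model.tol, model.n_iter, model.verbose)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(obs)
            ll = float(model.score(obs))
        if best is None or ll > best[0]:
            best = (ll, model)
    ll, model = best
    return StateModel(
        n_states=n_states,
        startprob=model.startprob_.copy(),
        transmat=model.transmat_.copy(),
        means=model.means_.copy(),
        covars=np.array(model.covars_),
        log_likelihood=ll,
        ll_history=list(model.monitor_.full_history),
        bic=float(model.bic(obs)),
        _hmm=model,
    )


def select_states(
    obs: np.ndarray,
    k_range: range = range(2, 13),
    criterion: str = "bic",
    seed: int = 0,
    n_init: int = 5,
    holdout_frac: float = 0.2,
    **fit_kwargs,
) -> StateModel:
    """Scan candidate state counts and return the model optimizing the
    criterion: ``'bic'`` (minimize; default) or ``'heldout'`` (maximize
    log-likelihood of the trailing ``holdout_frac`` split, models fitted on
    the rest).  All candidate scores are recorded on the returned model.
    """
    obs = np.asarray(obs, dtype=float)
    if criterion not in ("bic", "heldout"):
        raise ValueError(f"unknown criterion '{criterion}'")
    split = int(round(len(obs) * (1.0 - holdout_frac)))
    scores: dict[int, float] = {}
    models: dict[int, StateModel] = {}
    for k in k_range:
        if criterion == "bic":
            m = fit_hmm(obs, k, seed=seed, n_init=n_init, **fit_kwargs)
            scores[k] = m.bic
        else:
            m = fit_hmm(obs[:split], k, seed=seed, n_init=n_init, **fit_kwargs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores[k] = float(m._hmm.score(obs[split:]))
        models[k] = m
    if criterion == "bic":
        best_k = min(scores, key=lambda k: (scores[k], k))
    else:
        best_k = max(scores, key=lambda k: (scores[k], -k))
    best = models[best_k]
    best.selection_scores = scores
    best.criterion = criterion
    return best


# ---------------------------------------------------------------------------
# state-sequence metrics
# ---------------------------------------------------------------------------

@dataclass
class StateSequence:
    states: np.ndarray
    fps: float


def _run_lengths(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(run state, run length) pairs of a categorical sequence."""
    change = np.nonzero(np.diff(states))[0] + 1
    bounds = np.concatenate([[0], change, [len(states)]])
    return states[bounds[:-1]], np.diff(bounds)


def state_metrics(seq: StateSequence, n_states: int | None = None) -> dict:
    """Per-state occupancy, dwell time, stickiness, and transition matrices.

    * time_in_state_s: frames in state / fps; sums to session duration.
    * dwell_s: mean consecutive run length in seconds.
    * stickiness: self-transitions / outgoing transitions per state.
    * transition_counts: K x K frame-to-frame counts.
    * transition_norm: counts normalized so all entries sum to 1 (the
      display convention); transition_row is the row-stochastic variant.
    """
    states = np.asarray(seq.states, dtype=int)
    k = n_states if n_states is not None else int(states.max()) + 1
    counts = np.bincount(states, minlength=k).astype(float)
    time_in_state = counts / seq.fps

    run_states, run_lens = _run_lengths(states)
    dwell = np.full(k, np.nan)
    for s in range(k):
        m = run_states == s
        if m.any():
            dwell[s] = run_lens[m].mean() / seq.fps

    trans = np.zeros((k, k))
    np.add.at(trans, (states[:-1], states[1:]), 1.0)
    out = trans.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        stickiness = np.where(out > 0, np.diag(trans) / out, np.nan)
        row = np.where(out[:, None] > 0, trans / np.maximum(out[:, None], 1e-300), 0.0)
    total = trans.sum()
    norm = trans / total if total > 0 else trans
    return {
        "time_in_state_s": time_in_state,
        "dwell_s": dwell,
        "stickiness": stickiness,
        "transition_counts": trans,
        "transition_norm": norm,
        "transition_row": row,
    }
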