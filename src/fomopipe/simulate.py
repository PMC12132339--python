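"""Synthetic session generators with planted ground truth.

Every input the analysis stack consumes can be generated here: trial
schedules (60 trials; 10-s cue, 15-s transparent-wall window, 40-60-s ITI),
9-node pose tracks with interleaved attending/non-attending bouts near the
barrier, rendered grayscale frames for the behavior detector, calcium rasters
with planted response-profile clusters, two-channel photometry with a shared
motion artifact, and per-frame behavioral syllables.  Each generator records
the planted truth in a :class:`GroundTruth` container so every downstream
stage (state recovery, detection recall, responsiveness calibration, decoder
AUC, artifact removal) can be scored.

All randomness flows from ``SimConfig.seed`` through per-stage
``numpy.random.Generator`` instances; a fixed config reproduces outputs
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from fomopipe.features import ArenaConfig, KeypointTrack, NODE_NAMES, attending_geometry

# stage ids for per-stage child generators
_STAGE_SCHEDULE = 1
_STAGE_KEYPOINTS = 2
_STAGE_FRAMES = 3
_STAGE_NEURAL = 4
_STAGE_PHOTOMETRY = 5
_STAGE_SYLLABLES = 6
_STAGE_HMM = 7


@dataclass
class SimConfig:
    """Study conditions for one simulated session.

    Defaults follow the task structure of the social-exclusion paradigm:
    60 trials per session, 10-s tone cue, 15-s transparent-wall window,
    inter-trial intervals uniform in [40, 60] s after an initial 245-s
    habituation delay; video at 30 fps, calcium imaging at 10 Hz, photometry
    at 20 Hz per channel.
    """

    seed: int = 0
    n_trials: int = 60
    cue_s: float = 10.0
    wall_s: float = 15.0
    iti_range: tuple[float, float] = (40.0, 60.0)
    habituation_s: float = 245.0
    fps_video: float = 30.0
    fs_imaging: float = 10.0
    fs_photometry: float = 20.0
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    n_mice: int = 4

    # behavioral bout process
    p_trial_attend: float = 0.5  # fraction of trials planted as attending-heavy
    p_attend_cue: float = 0.9  # attending prob. per bout inside cue windows of those trials
    p_attend_iti: float = 0.05  # attending prob. per bout elsewhere
    bout_mean_s: float = 1.0
    missing_frac: float = 0.0
    keypoint_noise_px: float = 0.3

    # frame rendering
    frame_size: int = 64
    blob_sigma_px: float = 1.5

    # calcium raster
    n_neurons: int = 60
    neuron_cluster_profiles: tuple[tuple[str, int, float], ...] = (
        ("excited", 1, 0.3),
        ("inhibited", -1, 0.2),
        ("none", 0, 0.5),
    )
    neural_amp: float = 3.0
    neural_noise_sd: float = 1.0

    # photometry
    photometry_artifact_gain: float = 1.0
    photometry_artifact_amp: float = 0.5
    photometry_transient_amp: float = 1.0
    photometry_noise_sd: float = 0.02
    photometry_bleach_amp: float = 0.1  # signal channel; reference bleaches at 0.8x

    # syllables
    syllable_alphabet: int = 87
    syllable_dists: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.iti_range[0] > self.iti_range[1]:
            raise ValueError("iti_range must be (low, high) with low <= high")
        for name in ("fps_video", "fs_imaging", "fs_photometry", "cue_s", "wall_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        fracs = [f for _, _, f in self.neuron_cluster_profiles]
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("neuron_cluster_profiles fractions must sum to 1")

    def rng(self, stage: int) -> np.random.Generator:
        """Child generator for one pipeline stage (deterministic in seed)."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stage)]))


@dataclass
class TrialSchedule:
    """Cue onsets and window structure aligning all downstream analyses."""

    onsets_s: np.ndarray
    cue_s: float = 10.0
    wall_s: float = 15.0
    tail_s: float = 25.0  # recording continues past the last window

    @property
    def n_trials(self) -> int:
        return len(self.onsets_s)

    @property
    def duration_s(self) -> float:
        return float(self.onsets_s[-1] + self.wall_s + self.tail_s)


@dataclass
class GroundTruth:
    """Planted truth for one simulated session (the test oracle container)."""

    frame_state: np.ndarray | None = None  # per-frame bout state (1 = attending)
    attending_frames: np.ndarray | None = None  # per-frame geometry predicate
    trial_attending: np.ndarray | None = None  # per-trial planted flag
    clean_track: KeypointTrack | None = None  # pose before missingness injection
    detections: pd.DataFrame | None = None  # frame, class, x, y (arena pixels)
    neuron_cluster: np.ndarray | None = None  # per-neuron profile index
    neuron_sign: np.ndarray | None = None  # +1 excited / -1 inhibited / 0 null
    transient: np.ndarray | None = None  # true photometry transient trace
    artifact: np.ndarray | None = None  # shared photometry motion artifact


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def gen_schedule(cfg: SimConfig) -> TrialSchedule:
    """Trial onsets: habituation delay, then gaps = wall window + ITI draw."""
    rng = cfg.rng(_STAGE_SCHEDULE)
    itis = rng.uniform(cfg.iti_range[0], cfg.iti_range[1], size=max(cfg.n_trials - 1, 0))
    gaps = cfg.wall_s + itis
    onsets = cfg.habituation_s + np.concatenate([[0.0], np.cumsum(gaps)])
    return TrialSchedule(onsets_s=onsets, cue_s=cfg.cue_s, wall_s=cfg.wall_s)


# ---------------------------------------------------------------------------
# keypoints
# ---------------------------------------------------------------------------

def _unit(phi: np.ndarray | float) -> np.ndarray:
    return np.stack([np.cos(phi), np.sin(phi)], axis=-1)


def gen_keypoints(cfg: SimConfig, sched: TrialSchedule) -> tuple[KeypointTrack, GroundTruth]:
    """Pose track with a 2-state semi-Markov attending/other bout process.

    During attending bouts the nose relaxes to within barrier-contact
    distance of the barrier with the head oriented at the port; otherwise the
    mouse wanders its half of the arena.  A fraction ``missing_frac`` of
    coordinates is dropped (NaN) i.i.d. to exercise interpolation.  The
    returned :class:`GroundTruth` stores the bout states, the per-frame
    geometry predicate evaluated on the clean track, per-trial planted flags,
    and nose point labels for the detector.
    """
    rng = cfg.rng(_STAGE_KEYPOINTS)
    fps = cfg.fps_video
    n_frames = int(np.ceil(sched.duration_s * fps))
    arena = cfg.arena
    w, h = arena.image_size

    trial_attending = rng.random(sched.n_trials) < cfg.p_trial_attend

    # per-frame target attending probability
    p = np.full(n_frames, cfg.p_attend_iti)
    window_start = np.zeros(n_frames, dtype=bool)
    for i, on in enumerate(sched.onsets_s):
        a = int(round(on * fps))
        b = min(int(round((on + sched.wall_s) * fps)), n_frames)
        p[a:b] = cfg.p_attend_cue if trial_attending[i] else cfg.p_attend_iti
        window_start[a] = True
        if b < n_frames:
            window_start[b] = True

    # bout segmentation: geometric lengths, with forced cuts at window edges
    mean_len = max(cfg.bout_mean_s * fps, 1.0)
    state = np.zeros(n_frames, dtype=int)
    t = 0
    while t < n_frames:
        length = int(rng.geometric(1.0 / mean_len))
        end = min(t + max(length, 1), n_frames)
        cut = np.nonzero(window_start[t + 1 : end])[0]
        if cut.size:
            end = t + 1 + cut[0]
        state[t:end] = int(rng.random() < p[t])
        t = end

    # pose synthesis
    l_head, l_tail = 18.0, 25.0
    free_mu = np.array([0.35 * arena.barrier_x, h / 2.0])
    c = free_mu.copy()
    phi = rng.uniform(-np.pi, np.pi)
    port = np.asarray(arena.port_xy, dtype=float)
    centers = np.empty((n_frames, 2))
    phis = np.empty(n_frames)
    jitter = rng.uniform(-1.0, 1.0, n_frames)
    steps = rng.normal(0.0, 3.0, (n_frames, 2))
    dphis = rng.normal(0.0, 0.4, n_frames)
    nose_y_jit = rng.normal(0.0, 8.0, n_frames)
    for i in range(n_frames):
        if state[i]:
            ny = np.clip(port[1] + nose_y_jit[i], 10.0, h - 10.0)
            nose_target = np.array([arena.barrier_x - 0.4 * arena.barrier_contact_dist, ny])
            nose = centers[i - 1] + l_head * _unit(phis[i - 1]) if i else nose_target
            nose = nose + 0.6 * (nose_target - nose)
            aim = np.arctan2(port[1] - nose[1], port[0] - nose[0])
            phi = aim + 0.2 * arena.orient_angle_max * jitter[i]
            c = nose - l_head * _unit(phi)
        else:
            c = c + 0.08 * (free_mu - c) + steps[i]
            c[0] = np.clip(c[0], 15.0, arena.barrier_x - 2.5 * arena.barrier_contact_dist)
            c[1] = np.clip(c[1], 15.0, h - 15.0)
            phi = phi + dphis[i]
        centers[i] = c
        phis[i] = phi

    u = _unit(phis)
    nvec = np.stack([-u[:, 1], u[:, 0]], axis=1)
    coords = np.empty((n_frames, len(NODE_NAMES), 2))
    coords[:, 0] = centers + l_head * u  # nose
    coords[:, 1] = centers + 9.0 * u + 7.0 * nvec  # left_ear
    coords[:, 2] = centers + 9.0 * u - 7.0 * nvec  # right_ear
    coords[:, 3] = centers  # torso
    coords[:, 4] = centers + 6.0 * u + 8.0 * nvec
    coords[:, 5] = centers + 6.0 * u - 8.0 * nvec
    coords[:, 6] = centers - 10.0 * u + 9.0 * nvec
    coords[:, 7] = centers - 10.0 * u - 9.0 * nvec
    coords[:, 8] = centers - l_tail * u  # tail_base
    coords += rng.normal(0.0, cfg.keypoint_noise_px, coords.shape)
    coords[..., 0] = np.clip(coords[..., 0], 0.0, w - 1e-9)
    coords[..., 1] = np.clip(coords[..., 1], 0.0, h - 1e-9)

    clean = KeypointTrack(coords=coords.copy(), node_names=NODE_NAMES, fps=fps)
    attending = attending_geometry(clean, arena)
    frames_idx = np.nonzero(attending)[0]
    detections = pd.DataFrame(
        {
            "frame": frames_idx,
            "class": "attending",
            "x": coords[frames_idx, 0, 0],
            "y": coords[frames_idx, 0, 1],
        }
    )

    observed = coords.copy()
    if cfg.missing_frac > 0:
        mask = rng.random(observed.shape) < cfg.missing_frac
        observed[mask] = np.nan
    track = KeypointTrack(coords=observed, node_names=NODE_NAMES, fps=fps)
    truth = GroundTruth(
        frame_state=state,
        attending_frames=attending,
        trial_attending=trial_attending,
        clean_track=clean,
        detections=detections,
    )
    return track, truth


# ---------------------------------------------------------------------------
# rendered frames for the detector
# ---------------------------------------------------------------------------

def gen_frames(
    track: KeypointTrack,
    cfg: SimConfig,
    attending: np.ndarray | None = None,
) -> tuple[np.ndarray, list[list[tuple[str, float, float]]]]:
    """Render grayscale frames (Gaussian blobs at keypoints, faint barrier
    line) and point labels at the nose on attending frames.

    Coordinates are scaled from arena pixels to the rendered ``frame_size``;
    labels are in rendered pixel coordinates.  ``attending`` defaults to no
    labels.
    """
    size = cfg.frame_size
    w, h = cfg.arena.image_size
    sx, sy = size / w, size / h
    sigma = cfg.blob_sigma_px
    half = max(int(np.ceil(3 * sigma)), 1)
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    kernel = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))

    n = track.n_frames
    stack = np.zeros((n, size, size), dtype=np.float32)
    bx = int(round(cfg.arena.barrier_x * sx))
    if 0 <= bx < size:
        stack[:, :, bx] = 0.3
    amps = np.full(len(track.node_names), 0.6)
    amps[track.node_names.index("nose")] = 1.0
    coords = track.coords
    for i in range(n):
        img = stack[i]
        for j in range(coords.shape[1]):
            x, y = coords[i, j, 0] * sx, coords[i, j, 1] * sy
            if not np.isfinite(x) or not np.isfinite(y):
                continue
            cx, cy = int(round(x)), int(round(y))
            x0, x1 = max(cx - half, 0), min(cx + half + 1, size)
            y0, y1 = max(cy - half, 0), min(cy + half + 1, size)
            if x0 >= x1 or y0 >= y1:
                continue
            img[y0:y1, x0:x1] = np.maximum(
                img[y0:y1, x0:x1],
                amps[j] * kernel[y0 - cy + half : y1 - cy + half, x0 - cx + half : x1 - cx + half],
            )
    labels: list[list[tuple[str, float, float]]] = [[] for _ in range(n)]
    if attending is not None:
        nose = track.node("nose")
        for i in np.nonzero(np.asarray(attending, dtype=bool))[0]:
            x = float(np.clip(nose[i, 0] * sx, 0, size - 1))
            y = float(np.clip(nose[i, 1] * sy, 0, size - 1))
            labels[int(i)].append(("attending", x, y))
    return stack, labels


# ---------------------------------------------------------------------------
# calcium raster
# ---------------------------------------------------------------------------

def _alpha_template(fs: float, dur_s: float = 15.0, tau_s: float = 2.0) -> np.ndarray:
    t = np.arange(0.0, dur_s, 1.0 / fs)
    return (t / tau_s) * np.exp(1.0 - t / tau_s)


def gen_neural(cfg: SimConfig, sched: TrialSchedule, truth: GroundTruth | None = None):
    """Calcium raster at 10 Hz: each neuron is its planted response template
    convolved at the cue onsets plus Gaussian noise.

    Profiles (name, sign, fraction) come from
    ``cfg.neuron_cluster_profiles``; amplitudes vary +-20% around
    ``cfg.neural_amp``.  Cluster index and responsiveness sign are recorded
    in ``truth`` when given.  Returns a
    :class:`fomopipe.neural.NeuralSession`.
    """
    from fomopipe.neural import NeuralSession

    rng = cfg.rng(_STAGE_NEURAL)
    fs = cfg.fs_imaging
    n_t = int(np.ceil(sched.duration_s * fs))
    n_neurons = cfg.n_neurons

    fracs = np.array([f for _, _, f in cfg.neuron_cluster_profiles])
    counts = np.floor(fracs * n_neurons).astype(int)
    counts[-1] += n_neurons - counts.sum()
    cluster = np.repeat(np.arange(len(counts)), counts)
    rng.shuffle(cluster)
    signs = np.array([s for _, s, _ in cfg.neuron_cluster_profiles])[cluster]

    template = _alpha_template(fs)
    response = np.zeros(n_t)
    for on in sched.onsets_s:
        a = int(round(on * fs))
        b = min(a + len(template), n_t)
        response[a:b] += template[: b - a]

    amps = cfg.neural_amp * rng.uniform(0.8, 1.2, n_neurons) * signs
    dff = rng.normal(0.0, cfg.neural_noise_sd, (n_neurons, n_t))
    dff += amps[:, None] * response[None, :]

    if truth is not None:
        truth.neuron_cluster = cluster
        truth.neuron_sign = signs
    return NeuralSession(
        dff=dff,
        fs=fs,
        events={"cue": np.asarray(sched.onsets_s)},
        animal_id="sim",
        coreg_ids=np.arange(n_neurons),
    )


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

def gen_photometry(cfg: SimConfig, sched: TrialSchedule, truth: GroundTruth | None = None):
    """Two demultiplexed 20-Hz photometry channels with a shared motion
    artifact: transients appear only in the signal channel; the artifact
    appears in both with gain ``photometry_artifact_gain`` in the reference;
    both channels bleach slowly.

    Returns a :class:`fomopipe.photometry.PhotometrySession`.
    """
    from fomopipe.photometry import PhotometrySession

    rng = cfg.rng(_STAGE_PHOTOMETRY)
    fs = cfg.fs_photometry
    n = int(np.ceil(sched.duration_s * fs))
    t = np.arange(n) / fs

    bleach = cfg.photometry_bleach_amp * np.exp(-t / 600.0)
    artifact = gaussian_filter1d(rng.normal(0.0, 1.0, n), sigma=0.25 * fs)
    sd = artifact.std()
    if sd > 0:
        artifact = artifact / sd * cfg.photometry_artifact_amp

    tt = np.arange(0.0, 15.0, 1.0 / fs)
    template = (1.0 - np.exp(-tt / 0.2)) * np.exp(-tt / 2.0)
    template /= template.max()
    transient = np.zeros(n)
    for on in sched.onsets_s:
        a = int(round(on * fs))
        b = min(a + len(template), n)
        transient[a:b] += template[: b - a]
    transient *= cfg.photometry_transient_amp

    noise = cfg.photometry_noise_sd
    signal = 5.0 + bleach + transient + artifact + rng.normal(0.0, noise, n)
    reference = 4.0 + 0.8 * bleach + cfg.photometry_artifact_gain * artifact + rng.normal(0.0, noise, n)

    if truth is not None:
        truth.transient = transient
        truth.artifact = artifact
    return PhotometrySession(
        signal=signal,
        reference=reference,
        fs=fs,
        events=np.asarray(sched.onsets_s),
        sensor="DA",
    )


# ---------------------------------------------------------------------------
# syllables
# ---------------------------------------------------------------------------

def default_syllable_dists(n_states: int, alphabet: int) -> np.ndarray:
    """Per-state categorical emission distributions: 70% of the mass on the
    state's own contiguous syllable block, 30% uniform over the alphabet."""
    dists = np.full((n_states, alphabet), 0.3 / alphabet)
    block = alphabet // n_states
    for s in range(n_states):
        lo = s * block
        hi = alphabet if s == n_states - 1 else (s + 1) * block
        dists[s, lo:hi] += 0.7 / (hi - lo)
    return dists / dists.sum(axis=1, keepdims=True)


def gen_syllables(cfg: SimConfig, truth: GroundTruth) -> np.ndarray:
    """One syllable id per frame drawn from the true bout state's categorical
    emission distribution (default alphabet 87)."""
    if truth.frame_state is None:
        raise ValueError("truth must contain frame_state")
    states = np.asarray(truth.frame_state)
    dists = cfg.syllable_dists
    if dists is None:
        dists = default_syllable_dists(int(states.max()) + 1, cfg.syllable_alphabet)
    dists = np.asarray(dists, dtype=float)
    rng = cfg.rng(_STAGE_SYLLABLES)
    cum = np.cumsum(dists, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(len(states))
    out = np.empty(len(states), dtype=int)
    for s in np.unique(states):
        m = states == s
        out[m] = np.searchsorted(cum[s], u[m], side="right")
    return out


# ---------------------------------------------------------------------------
# planted Gaussian-emission HMM sequences (for state-model validation)
# ---------------------------------------------------------------------------

def default_state_params(
    n_states: int = 4,
    n_dims: int = 4,
    separation: float = 5.0,
    self_p: float = 0.95,
    seed: int = 0,
) -> dict:
    """Well-separated planted HMM: sticky transitions (self-transition
    ``self_p``) and unit-variance Gaussian emissions whose state means are
    at least ``separation`` within-state SDs apart, placed along mutually
    orthogonal directions (a collinear layout would let one elongated
    full-covariance Gaussian cover several states)."""
    rng = np.random.default_rng(seed)
    transmat = np.full((n_states, n_states), (1.0 - self_p) / max(n_states - 1, 1))
    np.fill_diagonal(transmat, self_p)
    g = rng.normal(0.0, 1.0, (n_states, n_dims))
    if n_states <= n_dims:
        q, _ = np.linalg.qr(g.T)
        means = q.T[:n_states] * (separation / np.sqrt(2.0))
    else:
        d = np.sqrt(((g[:, None, :] - g[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        means = g * (separation / d.min())
    means = means + rng.normal(0.0, 0.1, (n_states, n_dims))
    covars = np.tile(np.eye(n_dims), (n_states, 1, 1))
    startprob = np.full(n_states, 1.0 / n_states)
    return {"startprob": startprob, "transmat": transmat, "means": means, "covars": covars}


def gen_hmm_sequence(params: dict, n_frames: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Sample (observations, states) from planted Gaussian-HMM parameters."""
    rng = np.random.default_rng(seed)
    transmat = np.asarray(params["transmat"])
    means = np.asarray(params["means"])
    covars = np.asarray(params["covars"])
    startprob = np.asarray(params["startprob"])
    k, d = means.shape
    states = np.empty(n_frames, dtype=int)
    states[0] = rng.choice(k, p=startprob)
    for i in range(1, n_frames):
        states[i] = rng.choice(k, p=transmat[states[i - 1]])
    chols = np.linalg.cholesky(covars)
    z = rng.normal(0.0, 1.0, (n_frames, d))
    obs = means[states] + np.einsum("nij,nj->ni", chols[states], z)
    return obs, states
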