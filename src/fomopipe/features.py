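"""Pose-derived behavioral features for the trial-structured social paradigm.

Keypoint tracks (9-node mouse skeleton at 30 fps) are preprocessed
(interpolation of missing coordinates, centered moving-mean smoothing) and
turned into the continuous and discrete per-frame features used by every
downstream behavioral analysis: distance/angle to the reward port, body
velocity and acceleration, head/body/tail orientations, turning angle,
windowed tortuosity, nose-tail distance, arena zone, barrier contact and
port orientation flags, and huddle quality.

Conventions: image coordinates (origin top-left, y down), 0-based frame
indexing, angles in radians. ``angle_to_port`` is the unsigned angle in
[0, pi] between the head direction (ear-midpoint to nose) and the
nose-to-port vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

NODE_NAMES = (
    "nose",
    "left_ear",
    "right_ear",
    "torso",
    "left_forepaw",
    "right_forepaw",
    "left_hindpaw",
    "right_hindpaw",
    "tail_base",
)

#: continuous feature columns produced by :func:`compute_features`
CONTINUOUS_FEATURES = (
    "dist_to_port",
    "angle_to_port",
    "velocity",
    "acceleration",
    "head_body_angle",
    "head_tail_angle",
    "turning_angle",
    "tortuosity_1s",
    "tortuosity_5s",
    "nose_tail_dist",
    "d_nose_tail_dist",
)

#: discrete feature columns (not z-scored)
DISCRETE_FEATURES = (
    "zone",
    "oriented_to_port",
    "touching_barrier",
    "oriented_and_touching",
    "huddle_quality",
)

#: default observation set for the second-stage HMM: four listed continuous
#: features plus body acceleration, and the two discrete features
HMM_FEATURE_SUBSET = (
    "dist_to_port",
    "angle_to_port",
    "velocity",
    "turning_angle",
    "acceleration",
    "zone",
    "oriented_to_port",
)


@dataclass
class ArenaConfig:
    """Geometry of the divided arena, in image pixels.

    The barrier is the vertical line ``x = barrier_x``; the subject mouse
    lives on the low-x side and the reward port at ``port_xy`` on the far
    side.  ``zone_edges`` are two x-coordinates splitting the subject's view
    of the arena into 3 zones.  ``barrier_contact_dist`` and
    ``orient_angle_max`` parameterize the barrier-contact / port-orientation
    predicates.
    """

    port_xy: tuple[float, float] = (480.0, 240.0)
    barrier_x: float = 320.0
    zone_edges: tuple[float, float] = (107.0, 214.0)
    image_size: tuple[int, int] = (640, 480)  # (width, height)
    barrier_contact_dist: float = 30.0
    orient_angle_max: float = np.pi / 6

    def __post_init__(self) -> None:
        w, h = self.image_size
        if not (0 < self.zone_edges[0] < self.zone_edges[1] < w):
            raise ValueError("zone_edges must be strictly increasing and inside the image")
        if self.barrier_contact_dist <= 0 or self.orient_angle_max <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class KeypointTrack:
    """Per-frame body-part coordinates with skeleton metadata.

    coords has shape (frames, nodes, 2) in image pixels; missing
    coordinates are NaN until :func:`preprocess_keypoints` is applied.
    """

    coords: np.ndarray
    node_names: tuple[str, ...] = NODE_NAMES
    fps: float = 30.0
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (frames, nodes, 2)")
        if self.coords.shape[1] != len(self.node_names):
            raise ValueError("node_names length must match coords")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def node(self, name: str) -> np.ndarray:
        """(frames, 2) coordinates of one node."""
        return self.coords[:, self.node_names.index(name), :]


@dataclass
class FeatureMatrix:
    """Frames x features table with continuous/discrete kinds."""

    values: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)  # name -> continuous|discrete
    zscored: bool = False
    fps: float = 30.0

    @property
    def continuous_names(self) -> list[str]:
        return [c for c in self.values.columns if self.kinds.get(c) == "continuous"]

    @property
    def discrete_names(self) -> list[str]:
        return [c for c in self.values.columns if self.kinds.get(c) == "discrete"]


@dataclass
class TrialWindowSet:
    """Per-trial frame windows: [-5, 0) s baseline and three 5-s post bins."""

    baseline: np.ndarray  # (trials, 2) [start, stop) frame indices
    bins: np.ndarray  # (trials, 3, 2)
    fps: float

    @property
    def n_trials(self) -> int:
        return self.baseline.shape[0]

    def post_slice(self, trial: int) -> slice:
        """Frames of the full [0, 15) s post-onset window for one trial."""
        return slice(int(self.bins[trial, 0, 0]), int(self.bins[trial, -1, 1]))

    def post_mask(self, n_frames: int) -> np.ndarray:
        """Boolean mask of all post-onset frames across trials."""
        mask = np.zeros(n_frames, dtype=bool)
        for i in range(self.n_trials):
            s = self.post_slice(i)
            mask[s] = True
        return mask


def trial_windows(
    onsets_s: np.ndarray,
    fps: float,
    n_frames: int,
    baseline_s: float = 5.0,
    bin_s: float = 5.0,
    n_bins: int = 3,
) -> TrialWindowSet:
    """Frame-index windows around each cue onset.

    Baseline is [-baseline_s, 0) and the post-onset period [0, n_bins*bin_s)
    is partitioned into ``n_bins`` equal bins.  Raises if any window falls
    outside the recording.
    """
    onsets_s = np.asarray(onsets_s, dtype=float)
    on_f = np.round(onsets_s * fps).astype(int)
    nb = int(round(baseline_s * fps))
    nw = int(round(bin_s * fps))
    baseline = np.stack([on_f - nb, on_f], axis=1)
    bins = np.stack(
        [np.stack([on_f + b * nw, on_f + (b + 1) * nw], axis=1) for b in range(n_bins)],
        axis=1,
    )
    if baseline.min() < 0 or bins.max() > n_frames:
        raise ValueError("trial windows exceed recording bounds")
    return TrialWindowSet(baseline=baseline, bins=bins, fps=fps)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_keypoints(track: KeypointTrack, window_frames: int = 5) -> KeypointTrack:
    """Interpolate missing coordinates and smooth with a centered moving mean.

    Missing (NaN) values are filled by linear interpolation over time, with
    edge values held constant.  Smoothing uses a centered moving mean of
    ``window_frames`` (1 = no smoothing).  A node missing on every frame is
    an error.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    coords = track.coords.copy()
    n, k, _ = coords.shape
    for j in range(k):
        for d in range(2):
            col = coords[:, j, d]
            bad = np.isnan(col)
            if bad.all():
                raise ValueError(f"node '{track.node_names[j]}' is missing on every frame")
            if bad.any():
                idx = np.arange(n)
                col[bad] = np.interp(idx[bad], idx[~bad], col[~bad])
    if window_frames > 1:
        coords = _moving_mean(coords, window_frames)
    return replace(track, coords=coords, confidence=None)


def _moving_mean(coords: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean along axis 0 with shrinking edge windows."""
    n = coords.shape[0]
    half = window // 2
    csum = np.cumsum(coords, axis=0)
    csum = np.concatenate([np.zeros((1,) + coords.shape[1:]), csum], axis=0)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + (window - 1 - half), n - 1) + 1
    out = (csum[hi] - csum[lo]) / (hi - lo).reshape(-1, *([1] * (coords.ndim - 1)))
    return out


# ---------------------------------------------------------------------------
# geometry helpers (shared with the synthetic generator's truth predicate)
# ---------------------------------------------------------------------------

def _unsigned_angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Unsigned angle in [0, pi] between rows of u and v; 0 where either is 0."""
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    denom = nu * nv
    cosang = np.ones(np.broadcast_shapes(nu.shape, nv.shape))
    ok = denom > 0
    dot = np.sum(u * v, axis=-1)
    cosang = np.where(ok, np.divide(dot, denom, where=ok, out=np.ones_like(dot)), 1.0)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def head_direction(track: KeypointTrack) -> np.ndarray:
    """(frames, 2) vector from ear midpoint to nose."""
    mid = 0.5 * (track.node("left_ear") + track.node("right_ear"))
    return track.node("nose") - mid


def angle_to_port(track: KeypointTrack, arena: ArenaConfig) -> np.ndarray:
    """Unsigned angle between head direction and the nose-to-port vector."""
    hv = head_direction(track)
    pv = np.asarray(arena.port_xy) - track.node("nose")
    return _unsigned_angle(hv, pv)


def attending_geometry(track: KeypointTrack, arena: ArenaConfig) -> np.ndarray:
    """Boolean per-frame predicate: nose within barrier-contact distance of
    the barrier AND head oriented to the port within ``orient_angle_max``.

    This is the single geometric definition of "Attending" used both to plant
    ground truth in the synthetic generator and to derive the discrete
    ``oriented_and_touching`` feature, so the two agree frame-for-frame.
    """
    nose = track.node("nose")
    touching = np.abs(nose[:, 0] - arena.barrier_x) <= arena.barrier_contact_dist
    oriented = angle_to_port(track, arena) <= arena.orient_angle_max
    return touching & oriented


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def _tortuosity(xy: np.ndarray, window: int) -> np.ndarray:
    """Trailing-window tortuosity: path length / net displacement, >= 1.

    Frames with an incomplete trailing window, or where both path length and
    net displacement vanish, are assigned 1.0.
    """
    n = xy.shape[0]
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    cpath = np.concatenate([[0.0], np.cumsum(steps)])
    tort = np.ones(n)
    idx = np.arange(window, n)
    path = cpath[idx] - cpath[idx - window]
    net = np.linalg.norm(xy[idx] - xy[idx - window], axis=1)
    eps = 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.where(path < eps, 1.0, path / np.maximum(net, eps))
    tort[idx] = np.maximum(val, 1.0)
    return tort


def compute_features(
    track: KeypointTrack,
    arena: ArenaConfig,
    other_tracks: list[KeypointTrack] | None = None,
) -> FeatureMatrix:
    """Per-frame continuous and discrete behavioral features.

    Velocity/acceleration come from torso displacement (px/s, px/s^2);
    tortuosity over trailing 1-s and 5-s windows; discrete features are the
    arena zone of the torso (1-3), port orientation, barrier contact, their
    conjunction, and huddle quality (number of mice at the port; constant 0
    when no cagemate tracks are supplied).

    Parameters
    ----------
    track : preprocessed (NaN-free) keypoint track of the subject.
    arena : arena geometry.
    other_tracks : optional cagemate tracks for huddle quality.
    """
    if np.isnan(track.coords).any():
        raise ValueError("track contains missing values; run preprocess_keypoints first")
    w, h = arena.image_size
    finite = track.coords
    if finite[..., 0].max() > w or finite[..., 1].max() > h:
        raise ValueError("arena image_size inconsistent with track coordinates")

    fps = track.fps
    nose = track.node("nose")
    torso = track.node("torso")
    tail = track.node("tail_base")
    hv = head_direction(track)

    port = np.asarray(arena.port_xy)
    dist_to_port = np.linalg.norm(port - nose, axis=1)
    ang_port = angle_to_port(track, arena)

    disp = np.diff(torso, axis=0)
    speed = np.linalg.norm(disp, axis=1) * fps
    velocity = np.concatenate([[speed[0] if len(speed) else 0.0], speed])
    accel = np.concatenate([[0.0], np.diff(velocity)]) * fps

    body_vec = torso - tail
    head_body = _unsigned_angle(hv, body_vec)
    head_tail = _unsigned_angle(hv, nose - tail)

    heading = np.arctan2(disp[:, 1], disp[:, 0]) if len(disp) else np.zeros(0)
    dturn = np.diff(heading)
    dturn = np.arctan2(np.sin(dturn), np.cos(dturn))  # wrap to (-pi, pi]
    turning = np.concatenate([[0.0, 0.0], np.abs(dturn)])[: track.n_frames]

    tort1 = _tortuosity(torso, max(int(round(fps)), 1))
    tort5 = _tortuosity(torso, max(int(round(5 * fps)), 1))

    nose_tail = np.linalg.norm(nose - tail, axis=1)
    d_nose_tail = np.concatenate([[0.0], np.diff(nose_tail)])

    zone = np.digitize(torso[:, 0], bins=np.asarray(arena.zone_edges)) + 1
    oriented = (ang_port <= arena.orient_angle_max).astype(int)
    touching = (np.abs(nose[:, 0] - arena.barrier_x) <= arena.barrier_contact_dist).astype(int)
    oat = oriented & touching

    if other_tracks:
        at_port = sum(
            (np.linalg.norm(port - t.node("torso"), axis=1) < arena.barrier_contact_dist * 2).astype(int)
            for t in other_tracks
        )
        huddle = np.asarray(at_port)
    else:
        huddle = np.zeros(track.n_frames, dtype=int)

    values = pd.DataFrame(
        {
            "dist_to_port": dist_to_port,
            "angle_to_port": ang_port,
            "velocity": velocity,
            "acceleration": accel,
            "head_body_angle": head_body,
            "head_tail_angle": head_tail,
            "turning_angle": turning,
            "tortuosity_1s": tort1,
            "tortuosity_5s": tort5,
            "nose_tail_dist": nose_tail,
            "d_nose_tail_dist": d_nose_tail,
            "zone": zone,
            "oriented_to_port": oriented,
            "touching_barrier": touching,
            "oriented_and_touching": oat,
            "huddle_quality": huddle,
        }
    )
    kinds = {c: "continuous" for c in CONTINUOUS_FEATURES}
    kinds.update({c: "discrete" for c in DISCRETE_FEATURES})
    return FeatureMatrix(values=values, kinds=kinds, zscored=False, fps=fps)


def zscore_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Standardize continuous columns over the full session; discrete columns
    (and any constant huddle column) are untouched.

    Raises if a continuous column has zero variance, naming the column.
    """
    values = fm.values.copy()
    for c in fm.continuous_names:
        col = values[c].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        if sd == 0:
            raise ValueError(f"continuous feature '{c}' has zero variance")
        values[c] = (col - col.mean()) / sd
    return FeatureMatrix(values=values, kinds=dict(fm.kinds), zscored=True, fps=fm.fps)


# ---------------------------------------------------------------------------
# simple behavioral scores
# ---------------------------------------------------------------------------

def freeze_dash_score(
    fm: FeatureMatrix,
    v_thresh: float,
    a_thresh: float,
    dash_thresh: float,
    windows: TrialWindowSet | None = None,
) -> dict:
    """Per-frame freeze/dash labels and the dash/freeze ratio.

    A frame is *freezing* iff velocity < v_thresh and \\|acceleration\\| <
    a_thresh, and *dashing* iff velocity > dash_thresh.  The ratio counts
    dash vs freeze frames over the [0, 15) s post-cue windows when a window
    set is given (otherwise over the whole session); with zero freeze frames
    the ratio is returned as NaN (undefined), never infinite.
    """
    v = fm.values["velocity"].to_numpy(dtype=float)
    a = fm.values["acceleration"].to_numpy(dtype=float)
    freeze = (v < v_thresh) & (np.abs(a) < a_thresh)
    dash = v > dash_thresh
    if windows is not None:
        mask = windows.post_mask(len(v))
    else:
        mask = np.ones(len(v), dtype=bool)
    n_freeze = int(freeze[mask].sum())
    n_dash = int(dash[mask].sum())
    ratio = np.nan if n_freeze == 0 else n_dash / n_freeze
    return {
        "freeze": freeze,
        "dash": dash,
        "n_freeze": n_freeze,
        "n_dash": n_dash,
        "ratio": ratio,
    }


def reward_seeking(
    fm: FeatureMatrix,
    dist_thresh: float,
    windows: TrialWindowSet | None = None,
) -> np.ndarray | float:
    """Percent of frames with nose-port distance below threshold.

    With a window set: one percentage per trial over its [0, 15) s window;
    otherwise a single session-wide percentage.
    """
    d = fm.values["dist_to_port"].to_numpy(dtype=float)
    near = d < dist_thresh
    if windows is None:
        return 100.0 * near.mean() if len(near) else 0.0
    out = np.empty(windows.n_trials)
    for i in range(windows.n_trials):
        seg = near[windows.post_slice(i)]
        out[i] = 100.0 * seg.mean() if len(seg) else 0.0
    return out


def hotplate_scores(paradigm_value: float, baseline_value: float) -> tuple[float, float]:
    """Normalized (paradigm/baseline) and difference (paradigm-baseline)
    nocifensive scores; normalized is NaN when baseline is 0."""
    difference = paradigm_value - baseline_value
    normalized = np.nan if baseline_value == 0 else paradigm_value / baseline_value
    if baseline_value == 0:
        warnings.warn("baseline is 0; normalized score undefined", stacklevel=2)
    return normalized, difference
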