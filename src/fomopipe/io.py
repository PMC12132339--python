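"""File-format adapters: HDF5 keypoints and frames, CSV events/features/
matrices, JSON sidecars.  No module mutates its inputs; writers create
parent directories as needed."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from fomopipe.features import FeatureMatrix, KeypointTrack
from fomopipe.simulate import TrialSchedule


def _prep(path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


# -- keypoints ---------------------------------------------------------------

def write_keypoints_h5(path, track: KeypointTrack) -> None:
    """Layout: datasets ``tracks`` (frames x nodes x 2), ``node_names``;
    fps stored as a root attribute."""
    with h5py.File(_prep(path), "w") as f:
        f.create_dataset("tracks", data=track.coords)
        f.create_dataset("node_names", data=np.array([n.encode() for n in track.node_names]))
        f.attrs["fps"] = track.fps


def read_keypoints_h5(path) -> KeypointTrack:
    with h5py.File(path, "r") as f:
        coords = f["tracks"][()]
        names = tuple(n.decode() for n in f["node_names"][()])
        fps = float(f.attrs["fps"])
    return KeypointTrack(coords=coords, node_names=names, fps=fps)


def write_keypoints_csv(path, track: KeypointTrack) -> None:
    """Long form: frame, node, x, y."""
    n, k, _ = track.coords.shape
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n), k),
            "node": list(track.node_names) * n,
            "x": track.coords[:, :, 0].ravel(),
            "y": track.coords[:, :, 1].ravel(),
        }
    )
    df.to_csv(_prep(path), index=False)


# -- schedule / events -------------------------------------------------------

def write_schedule_csv(path, sched: TrialSchedule) -> None:
    df = pd.DataFrame({"trial": np.arange(sched.n_trials), "onset_s": sched.onsets_s})
    df["cue_s"] = sched.cue_s
    df["wall_s"] = sched.wall_s
    df.to_csv(_prep(path), index=False)


def read_schedule_csv(path) -> TrialSchedule:
    df = pd.read_csv(path)
    return TrialSchedule(
        onsets_s=df["onset_s"].to_numpy(),
        cue_s=float(df["cue_s"].iloc[0]) if "cue_s" in df else 10.0,
        wall_s=float(df["wall_s"].iloc[0]) if "wall_s" in df else 15.0,
    )


# -- features ----------------------------------------------------------------

def write_features_csv(path, fm: FeatureMatrix) -> None:
    """CSV of the feature table plus a ``.kinds.json`` sidecar recording
    continuous/discrete kinds, fps and the z-scored flag."""
    path = _prep(path)
    fm.values.to_csv(path, index=False)
    sidecar = {"kinds": fm.kinds, "zscored": fm.zscored, "fps": fm.fps}
    Path(str(path) + ".kinds.json").write_text(json.dumps(sidecar, indent=1))


def read_features_csv(path) -> FeatureMatrix:
    values = pd.read_csv(path)
    sidecar = json.loads(Path(str(path) + ".kinds.json").read_text())
    return FeatureMatrix(
        values=values, kinds=sidecar["kinds"], zscored=sidecar["zscored"], fps=sidecar["fps"]
    )


# -- matrices / traces -------------------------------------------------------

def write_raster_csv(path, dff: np.ndarray, coreg_ids: np.ndarray | None = None) -> None:
    df = pd.DataFrame(np.asarray(dff))
    df.insert(0, "coreg_id", coreg_ids if coreg_ids is not None else np.arange(len(df)))
    df.to_csv(_prep(path), index=False)


def read_raster_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    coreg = df.pop("coreg_id").to_numpy()
    return df.to_numpy(dtype=float), coreg


def write_traces_csv(path, t: np.ndarray, signal: np.ndarray, reference: np.ndarray) -> None:
    pd.DataFrame({"t": t, "signal": signal, "reference": reference}).to_csv(_prep(path), index=False)


def read_traces_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- frames and labels -------------------------------------------------------

def write_frames_h5(path, stack: np.ndarray) -> None:
    with h5py.File(_prep(path), "w") as f:
        f.create_dataset("frames", data=np.asarray(stack, dtype=np.float32), compression="gzip")


def read_frames_h5(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["frames"][()]


def write_labels_csv(path, labels) -> None:
    """Point-annotation export style: frame, class, x, y."""
    rows = [(i, c, x, y) for i, fl in enumerate(labels) for c, x, y in fl]
    pd.DataFrame(rows, columns=["frame", "class", "x", "y"]).to_csv(_prep(path), index=False)


def read_labels_csv(path, n_frames: int):
    df = pd.read_csv(path)
    labels = [[] for _ in range(n_frames)]
    for _, r in df.iterrows():
        labels[int(r["frame"])].append((r["class"], float(r["x"]), float(r["y"])))
    return labels


def write_ethogram_csv(path, ethogram: np.ndarray, classes=("attending",)) -> None:
    eth = np.asarray(ethogram, dtype=int)
    if eth.ndim == 1:
        eth = eth[:, None]
    df = pd.DataFrame(eth, columns=list(classes))
    df.insert(0, "frame", np.arange(len(df)))
    df.to_csv(_prep(path), index=False)
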