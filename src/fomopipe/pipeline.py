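"""End-to-end pipeline driver: configuration, input validation, stage
orchestration, and a reproducibility manifest.

``run_pipeline`` executes the stages in dependency order on a synthetic (or
previously written) session: simulate -> features -> attending detection ->
trial labels -> photometry correction/decoding -> calcium PSTH and
responsiveness.  Every output file is hashed into a manifest; deterministic
stages reproduce identical hashes on rerun with the same config.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fomopipe import detect, io, neural, photometry
from fomopipe.features import (
    NODE_NAMES,
    attending_geometry,
    compute_features,
    preprocess_keypoints,
    zscore_features,
)
from fomopipe.simulate import (
    GroundTruth,
    SimConfig,
    gen_frames,
    gen_keypoints,
    gen_neural,
    gen_photometry,
    gen_schedule,
)

CONDITIONS = ("SE", "OM", "TO")


@dataclass
class PipelineConfig:
    """Single structured config driving a full run; unknown keys rejected."""

    seed: int = 0
    condition: str = "SE"
    out_dir: str = "fomopipe_out"
    n_trials: int = 60
    use_detector: bool = False  # geometry-predicate ethogram when False
    detector_epochs: int = 5
    detector_conf: float = 0.5
    detector_radius_px: float = 6.0
    smoothing_window: int = 5
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, n_trials=self.n_trials, **self.sim_overrides)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(paths: dict[str, str]) -> list[str]:
    """Schema checks for pipeline input files; returns violation strings
    (empty = all well-formed).  Report-only: never raises for content."""
    violations: list[str] = []
    for kind, path in paths.items():
        p = Path(path)
        if not p.exists():
            violations.append(f"{kind}: file not found: {p}")
            continue
        try:
            if kind == "events":
                df = pd.read_csv(p)
                for col in ("trial", "onset_s"):
                    if col not in df:
                        violations.append(f"events: missing column '{col}'")
                if "onset_s" in df and not df["onset_s"].is_monotonic_increasing:
                    violations.append("events: onset_s not strictly increasing")
            elif kind == "keypoints":
                track = io.read_keypoints_h5(p)
                if track.coords.shape[1] != len(NODE_NAMES):
                    violations.append(
                        f"keypoints: expected {len(NODE_NAMES)} nodes, got {track.coords.shape[1]}"
                    )
            elif kind == "traces":
                df = pd.read_csv(p)
                for col in ("t", "signal", "reference"):
                    if col not in df:
                        violations.append(f"traces: missing column '{col}'")
        except Exception as e:  # malformed file is a violation, not a crash
            violations.append(f"{kind}: unreadable ({e})")
    return violations


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages on a simulated session; returns the manifest dict
    (also written to ``out_dir/manifest.json``)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "outputs": {}, "warnings": [], "config": asdict(cfg)}

    def stage(name: str, fn):
        t0 = time.time()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fn()
        manifest["stages"].append({"name": name, "wall_s": round(time.time() - t0, 3)})
        manifest["warnings"].extend(f"{name}: {w.message}" for w in caught)

    sim = cfg.sim_config()
    state: dict = {}

    def do_simulate():
        sched = gen_schedule(sim)
        track, truth = gen_keypoints(sim, sched)
        state.update(sched=sched, track=track, truth=truth)
        io.write_schedule_csv(out / "events.csv", sched)
        io.write_keypoints_h5(out / "keypoints.h5", track)

    def do_features():
        track = preprocess_keypoints(state["track"], window_frames=cfg.smoothing_window)
        fm = compute_features(track, sim.arena)
        state["fm"] = zscore_features(fm)
        state["clean_fm"] = fm
        io.write_features_csv(out / "features.csv", fm)

    def do_detect():
        truth: GroundTruth = state["truth"]
        if cfg.use_detector:
            stack, labels = gen_frames(truth.clean_track, sim, attending=truth.attending_frames)
            targets = detect.make_heatmap_targets(labels, sim.frame_size)
            model = detect.train_detector(stack, targets, epochs=cfg.detector_epochs, seed=cfg.seed)
            eth, dets = detect.classify_frames(
                model, stack, conf_thresh=cfg.detector_conf, radius_px=cfg.detector_radius_px
            )
            ethogram = eth[:, 0]
            dets.to_csv(out / "detections.csv", index=False)
        else:
            ethogram = attending_geometry(truth.clean_track, sim.arena)
        state["ethogram"] = ethogram
        io.write_ethogram_csv(out / "ethogram.csv", ethogram)

    def do_label_trials():
        ta = detect.quantify_attending(state["ethogram"], state["sched"], sim.fps_video)
        labels, thr = detect.label_trials(ta.total_counts, mode="local")
        ta.table["label"] = np.where(labels, "attending", "not_attending")
        ta.table["threshold_used"] = "local"
        ta.table["threshold"] = thr
        state["attendance"] = ta
        ta.table.to_csv(out / "trial_attendance.csv", index=False)

    def do_photometry():
        truth = state["truth"]
        sess = gen_photometry(sim, state["sched"], truth)
        ct = photometry.regress_reference(sess)
        auc = photometry.trial_auc(ct, sensor=sess.sensor)
        auc.to_csv(out / "photometry_auc.csv", index=False)
        state["corrected"] = ct

    def do_neural():
        truth = state["truth"]
        sess = gen_neural(sim, state["sched"], truth)
        psth = neural.compute_psth(sess, sess.events["cue"])
        resp = neural.call_responsive(psth)
        resp.to_csv(out / "responsiveness.csv", index=False)
        io.write_raster_csv(out / "raster.csv", sess.dff, sess.coreg_ids)

    stage("simulate", do_simulate)
    stage("features", do_features)
    stage("detect", do_detect)
    stage("label-trials", do_label_trials)
    stage("photometry", do_photometry)
    stage("neural", do_neural)

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
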