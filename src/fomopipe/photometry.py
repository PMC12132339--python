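"""Biosensor fiber-photometry processing and trial-level decoding.

Two demultiplexed 20-Hz channels per session: a ligand-sensitive signal
channel (470 nm) and a ligand-insensitive reference channel (405/415 nm)
that carries the same motion/bleaching artifact.  Processing follows the
standard reference-regression recipe: both channels are median-filtered with
a causal 200-ms window; regression coefficients (slope, intercept) are fit
by least squares on the trial-averaged [-1, 0) s pre-cue baseline segments
(to keep evoked transients out of the fit); the fitted reference projection
is subtracted from the signal over the whole session; and each trial's
corrected trace is z-transformed against its own [-1, 0) s baseline.

Trial metrics are trapezoidal AUCs of the z-trace over sensor-specific
windows (0-20 s for dopamine and oxytocin sensors, 0-15 s for the
endocannabinoid sensor, reflecting sensor kinetics).  A random-forest
classifier decodes attending vs not-attending trials from (trial,
timepoint) samples pooled over a window, with trial-level 5-fold
cross-validation and a shuffled-label control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

#: default AUC windows (s post cue) by sensor tag
SENSOR_AUC_WINDOWS = {"DA": (0.0, 20.0), "OXT": (0.0, 20.0), "eCB": (0.0, 15.0)}


@dataclass
class PhotometrySession:
    """Demultiplexed signal/reference traces with cue-onset events."""

    signal: np.ndarray
    reference: np.ndarray
    fs: float
    events: np.ndarray  # cue onsets (s)
    sensor: str = "DA"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.signal.shape != self.reference.shape:
            raise ValueError("signal and reference must have equal length")


@dataclass
class CorrectedTrace:
    """Per-trial residual z-traces with the session regression coefficients."""

    z: np.ndarray  # (trials, samples) over the extraction window
    t: np.ndarray  # sample times relative to cue onset (s)
    slope: float
    intercept: float
    fs: float
    baseline_window: tuple[float, float] = (-1.0, 0.0)
    corrected_full: np.ndarray | None = None  # whole-session corrected trace


def median_filter(trace: np.ndarray, fs: float, span_s: float = 0.2) -> np.ndarray:
    """Forward-only (causal, trailing-window) median filter.

    The window covers the current sample and the preceding ``span_s``
    seconds' worth of samples; early samples use the available partial
    window.
    """
    window = max(int(round(span_s * fs)), 1)
    s = pd.Series(np.asarray(trace, dtype=float))
    return s.rolling(window, min_periods=1).median().to_numpy()


def regress_reference(
    sess: PhotometrySession,
    window: tuple[float, float] = (-5.0, 20.0),
    baseline: tuple[float, float] = (-1.0, 0.0),
    filter_span_s: float | None = 0.2,
) -> CorrectedTrace:
    """Reference-regression correction and per-trial z-transform.

    Both channels are (optionally) median-filtered, then a single
    slope/intercept pair is fit by ordinary least squares on the
    trial-averaged baseline-window segments (reference -> signal) and the
    fitted reference projection is subtracted from the signal over the whole
    session.  Each trial's corrected trace over ``window`` is z-scored
    against its own baseline samples, so the baseline has mean 0 and SD 1 by
    construction.
    """
    if len(sess.events) < 2:
        raise ValueError("need at least 2 trials to fit regression coefficients")
    fs = sess.fs
    sig = median_filter(sess.signal, fs, filter_span_s) if filter_span_s else sess.signal.copy()
    ref = median_filter(sess.reference, fs, filter_span_s) if filter_span_s else sess.reference.copy()

    nb0 = int(round(baseline[0] * fs))
    nb1 = int(round(baseline[1] * fs))
    seg_sig, seg_ref = [], []
    for ev in sess.events:
        c = int(round(ev * fs))
        if c + nb0 < 0 or c + nb1 > len(sig):
            raise ValueError("baseline window exceeds trace bounds")
        seg_sig.append(sig[c + nb0 : c + nb1])
        seg_ref.append(ref[c + nb0 : c + nb1])
    avg_sig = np.mean(seg_sig, axis=0)
    avg_ref = np.mean(seg_ref, axis=0)
    if avg_ref.std() == 0:
        warnings.warn("reference variance is zero in the fit window; slope set to 0")
        slope, intercept = 0.0, float(avg_sig.mean())
    else:
        slope, intercept = np.polyfit(avg_ref, avg_sig, 1)
    corrected = sig - (slope * ref + intercept)

    n0 = int(round(window[0] * fs))
    n1 = int(round(window[1] * fs)) + 1  # right endpoint inclusive
    t = np.arange(n0, n1) / fs
    bmask = (t >= baseline[0]) & (t < baseline[1])
    zs = []
    for ev in sess.events:
        c = int(round(ev * fs))
        if c + n0 < 0 or c + n1 > len(corrected):
            raise ValueError("extraction window exceeds trace bounds")
        seg = corrected[c + n0 : c + n1]
        mu = seg[bmask].mean()
        sd = seg[bmask].std(ddof=0)
        if sd == 0:
            warnings.warn("zero baseline SD in a trial; z undefined, returning NaN")
            zs.append(np.full_like(seg, np.nan))
        else:
            zs.append((seg - mu) / sd)
    return CorrectedTrace(
        z=np.stack(zs),
        t=t,
        slope=float(slope),
        intercept=float(intercept),
        fs=fs,
        baseline_window=baseline,
        corrected_full=corrected,
    )


def trial_auc(
    ct: CorrectedTrace,
    window: tuple[float, float] | None = None,
    sensor: str = "DA",
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Trapezoidal AUC of each trial's z-trace over the sensor window.

    ``window`` defaults to the sensor-specific preset (0-20 s for DA/OXT,
    0-15 s for eCB).  Optional attending/not labels are attached per trial.
    """
    if window is None:
        window = SENSOR_AUC_WINDOWS[sensor]
    mask = (ct.t >= window[0]) & (ct.t <= window[1])
    if not mask.any() or ct.t[-1] < window[1] - 1.0 / ct.fs:
        raise ValueError("AUC window exceeds extracted trace")
    dt = 1.0 / ct.fs
    aucs = np.trapezoid(ct.z[:, mask], dx=dt, axis=1)
    out = pd.DataFrame({"trial": np.arange(ct.z.shape[0]), "auc": aucs})
    if labels is not None:
        out["label"] = np.asarray(labels)
    return out


@dataclass
class RFDecodingResult:
    auroc: float
    shuffled_auroc: float
    fold_trials: list[np.ndarray]  # trial indices per test fold


def rf_decode(
    z_trials: np.ndarray,
    labels: np.ndarray,
    t: np.ndarray,
    window: tuple[float, float] = (0.0, 15.0),
    folds: int = 5,
    seed: int = 0,
    n_trees: int = 500,
    max_depth: int | None = None,
) -> RFDecodingResult:
    """Random-forest decoding of trial labels from pooled timepoints.

    Samples are (trial, timepoint) pairs within the window, with the z value
    at that timepoint as the feature.  Cross-validation is partitioned at
    the trial level (no trial contributes to both train and test), and all
    pooled held-out predictions form a single ROC.  The shuffled control
    permutes training labels at the trial level with the same folds.
    """
    z_trials = np.asarray(z_trials, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    mask = (t >= window[0]) & (t < window[1])
    x = z_trials[:, mask]
    n_trials = x.shape[0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_trials)
    fold_ids = np.empty(n_trials, dtype=int)
    for f in range(folds):
        fold_ids[order[f::folds]] = f

    def run(shuffle: bool) -> float:
        scores = np.empty(0)
        truth = np.empty(0, dtype=bool)
        for f in range(folds):
            te = fold_ids == f
            tr = ~te
            y_tr = labels[tr].copy()
            if shuffle:
                rng2 = np.random.default_rng(seed * 100 + f)
                rng2.shuffle(y_tr)
            xf_tr = x[tr].reshape(-1, 1)
            yf_tr = np.repeat(y_tr, x.shape[1])
            clf = RandomForestClassifier(n_estimators=n_trees, max_depth=max_depth, random_state=seed)
            clf.fit(xf_tr, yf_tr)
            p = clf.predict_proba(x[te].reshape(-1, 1))[:, 1]
            scores = np.concatenate([scores, p])
            truth = np.concatenate([truth, np.repeat(labels[te], x.shape[1])])
        return float(roc_auc_score(truth, scores))

    return RFDecodingResult(
        auroc=run(False),
        shuffled_auroc=run(True),
        fold_trials=[np.nonzero(fold_ids == f)[0] for f in range(folds)],
    )
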