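"""Arrhythmic-beat editing.

Ectopic beats bias HRV spectra (they inflate high-frequency power and
time-domain dispersion), so before any spectral analysis the RR stream is
edited: beats are classified sinus/abnormal from six morphology-and-rhythm
features with an SVM, 10-minute segments with under 80% normal beats are
excluded wholesale, and the remaining abnormal intervals (ectopic plus its
compensatory pause) are replaced by nonlinear predictive interpolation — the
interval that historically followed the 10-interval pattern most similar to
the 10 intervals preceding the gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocess import ECGRecord, PeakList, RRSeries

FEATURE_COLUMNS = ["r_amp", "dt_prev", "dt_next", "mean_rr10", "phase", "qrs_dur"]


@dataclass
class BeatLabels:
    """Per-beat sinus/abnormal call and where it came from."""

    labels: np.ndarray  # 'sinus' | 'abnormal'
    source: str  # 'classifier' | 'annotation'


@dataclass
class ClassifierModel:
    """Trained decision function over the six beat features."""

    pipeline: Pipeline
    feature_columns: list[str]
    training_meta: dict

    def predict(self, features: pd.DataFrame) -> BeatLabels:
        X = features[self.feature_columns].to_numpy(dtype=float)
        ok = np.isfinite(X).all(axis=1)
        labels = np.full(len(X), "sinus", dtype=object)
        if ok.any():
            labels[ok] = self.pipeline.predict(X[ok])
        return BeatLabels(labels=labels, source="classifier")


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def extract_beat_features(record: ECGRecord, peaks: PeakList,
                          qrs_bounds: tuple[np.ndarray, np.ndarray] | None = None) -> pd.DataFrame:
    """Six per-beat features: R amplitude, previous/next RR, trailing-10 mean
    RR, R-peak phase, and QRS duration.

    Phase is the beat's prematurity: dt_prev / mean_rr10 wrapped into [0, 1).
    Edge beats that lack a previous/next interval or a full 10-beat history
    carry NaN in the affected columns (explicit missing markers).
    """
    idx = np.asarray(peaks.indices)
    if len(idx) < 11:
        raise ValueError("need at least 11 beats for the 10-beat mean RR feature")
    x = np.asarray(record.samples, dtype=float)
    fs = float(record.fs)
    times_ms = idx / fs * 1000.0
    n = len(idx)

    r_amp = np.abs(x[idx])
    dt_prev = np.full(n, np.nan)
    dt_next = np.full(n, np.nan)
    dt_prev[1:] = np.diff(times_ms)
    dt_next[:-1] = np.diff(times_ms)

    mean_rr10 = np.full(n, np.nan)
    for i in range(10, n):
        mean_rr10[i] = (times_ms[i] - times_ms[i - 10]) / 10.0

    with np.errstate(invalid="ignore", divide="ignore"):
        phase = np.mod(dt_prev / mean_rr10, 1.0)

    if qrs_bounds is not None:
        onsets, offsets = qrs_bounds
        qrs_dur = (np.asarray(offsets) - np.asarray(onsets)) / fs * 1000.0
        qrs_dur = np.where(qrs_dur > 0, qrs_dur, np.nan)
    else:
        qrs_dur = _qrs_duration_estimate(x, idx, fs)

    return pd.DataFrame({
        "r_amp": r_amp, "dt_prev": dt_prev, "dt_next": dt_next,
        "mean_rr10": mean_rr10, "phase": phase, "qrs_dur": qrs_dur,
    })


def _qrs_duration_estimate(x: np.ndarray, idx: np.ndarray, fs: float,
                           window_s: float = 0.150, frac: float = 0.02) -> np.ndarray:
    """Width of the region around each R peak where |slope| exceeds a small
    fraction of the beat's maximal |slope|."""
    h = int(round(window_s * fs))
    out = np.full(len(idx), np.nan)
    for k, i in enumerate(idx):
        lo, hi = max(0, i - h), min(len(x) - 1, i + h)
        seg = x[lo:hi + 1]
        if len(seg) < 5:
            continue
        d = np.abs(np.gradient(seg)) * fs
        thr = frac * d.max()
        above = np.flatnonzero(d > thr)
        if len(above) == 0:
            continue
        out[k] = (above[-1] - above[0]) / fs * 1000.0
    return out


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

def train_beat_classifier(features: pd.DataFrame, labels: np.ndarray,
                          C: float = 10.0, gamma: str | float = "scale",
                          class_weight: str | dict | None = "balanced",
                          seed: int = 0) -> ClassifierModel:
    """Standardized RBF-SVM over the six features.

    Rows with missing features (edge beats) are dropped from training.
    """
    X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=object)
    ok = np.isfinite(X).all(axis=1)
    X, y = X[ok], y[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(C=C, gamma=gamma, kernel="rbf", class_weight=class_weight,
                    random_state=seed)),
    ])
    pipe.fit(X, y)
    meta = {"n_train": int(len(y)),
            "class_counts": {str(c): int((y == c).sum()) for c in np.unique(y)},
            "C": C, "gamma": str(gamma)}
    return ClassifierModel(pipeline=pipe, feature_columns=list(FEATURE_COLUMNS),
                           training_meta=meta)


# ---------------------------------------------------------------------------
# segment exclusion
# ---------------------------------------------------------------------------

def exclude_low_quality_segments(labels: BeatLabels | np.ndarray,
                                 beat_times: np.ndarray,
                                 segment_len_s: float = 600.0,
                                 min_normal: float = 0.80) -> np.ndarray:
    """Flag all beats of any 10-min window with < 80% normal beats.

    Windows tile the record from t = 0; the 'less than' is strict, so a
    window at exactly the threshold is kept.  Returns a per-beat boolean
    exclusion mask.
    """
    lab = labels.labels if isinstance(labels, BeatLabels) else np.asarray(labels, dtype=object)
    beat_times = np.asarray(beat_times, dtype=float)
    if np.any(np.diff(beat_times) < 0):
        raise ValueError("beat_times must be sorted")
    excluded = np.zeros(len(beat_times), dtype=bool)
    seg = np.floor(beat_times / segment_len_s).astype(int)
    for s in np.unique(seg):
        m = seg == s
        frac_normal = np.mean(lab[m] == "sinus")
        if frac_normal < min_normal:
            excluded[m] = True
    return excluded


# ---------------------------------------------------------------------------
# nonlinear predictive interpolation
# ---------------------------------------------------------------------------

def predictive_interpolate(rr: RRSeries, abnormal: np.ndarray,
                           template_len: int = 10) -> RRSeries:
    """Replace abnormal RR intervals by the template-following value.

    For each abnormal interval (left to right): the query is the 10 intervals
    immediately before it, using already-corrected values; the templates are
    all runs of 10 consecutive originally-normal intervals whose follower is
    also normal and which do not overlap the query or any abnormal interval;
    the replacement is the interval following the template nearest to the
    query in Euclidean distance (ties broken by the earliest template start).
    Abnormal intervals with no preceding 10-window or no eligible template
    are left in place and flagged 'excluded'.
    """
    abnormal = np.asarray(abnormal, dtype=bool)
    vals = rr.rr.astype(float).copy()
    status = rr.status.copy()
    n = len(vals)
    if abnormal.shape != (n,):
        raise ValueError("abnormal mask must match the number of intervals")
    normal_orig = ~abnormal

    # eligible template starts: 11 consecutive originally-normal intervals.
    # Normal intervals are never modified, so the template bank is static.
    if n > template_len:
        norm_f = normal_orig.astype(float)
        csum = np.concatenate([[0.0], np.cumsum(norm_f)])
        runs = csum[template_len + 1:] - csum[:-template_len - 1]
        ok_run = runs == template_len + 1  # starts of 11 all-normal intervals
    else:
        ok_run = np.zeros(0, dtype=bool)
    starts = np.flatnonzero(ok_run)

    if normal_orig.sum() < 2 * template_len + 1:
        raise ValueError("need at least 21 normal RR intervals")

    templates = np.lib.stride_tricks.sliding_window_view(vals, template_len)[starts] \
        if len(starts) else np.zeros((0, template_len))
    followers = vals[starts + template_len] if len(starts) else np.zeros(0)

    for i in np.flatnonzero(abnormal):
        if i < template_len:
            status[i] = "excluded"
            continue
        query = vals[i - template_len:i]
        if np.any(status[i - template_len:i] == "excluded"):
            status[i] = "excluded"
            continue
        # drop templates overlapping the query or the abnormal interval
        eligible = (starts + template_len < i - template_len) | (starts > i)
        if not eligible.any():
            status[i] = "excluded"
            continue
        d = np.sum((templates[eligible] - query[None, :]) ** 2, axis=1)
        best = int(np.argmin(d))  # argmin takes the earliest start on ties
        vals[i] = followers[eligible][best]
        status[i] = "interpolated"

    beat_times = rr.beat_times[0] + np.concatenate([[0.0], np.cumsum(vals)]) / 1000.0
    return RRSeries(beat_times=beat_times, rr=vals, status=status)
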