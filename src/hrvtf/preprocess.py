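"""Raw-ECG standardization and RR-series construction.

The chain is: resample to 500 Hz (cubic spline) if slower, remove mains
interference with a notch filter, subtract a 500 ms running-median baseline;
detect R peaks with a Pan-Tompkins-style detector (bandpass, derivative,
squaring, moving integration, adaptive threshold) enforcing a 250 ms
refractory period that keeps the steeper-slope peak; then correct the RR
sequence against a running 5-interval median — intervals below 0.5x the
median whose sum with a neighbor restores the median are merged (spurious
peak deleted), intervals above 2x the median are split into k = round(rr/m)
equal parts (missed beats re-inserted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import maximum_filter1d, median_filter, uniform_filter1d
from scipy.signal import butter, find_peaks, iirnotch, filtfilt, sosfiltfilt

TARGET_FS = 500.0
REFRACTORY_S = 0.250


@dataclass
class ECGRecord:
    """Uniformly sampled single-lead voltage trace."""

    samples: np.ndarray  # mV
    fs: float
    start_time: float = 0.0
    lead: str = ""

    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class PeakList:
    """Detected R peaks with per-peak maximal |dV/dt|."""

    indices: np.ndarray  # strictly increasing sample indices
    slopes: np.ndarray  # mV/s
    fs: float


@dataclass
class RRSeries:
    """Per-beat interval sequence with status flags.

    beat_times has one more entry than rr; rr[i] spans beat_times[i] to
    beat_times[i+1].  status flags are per interval: 'normal',
    'removed-spurious-merge', 'split-inserted', 'interpolated', 'excluded'.
    """

    beat_times: np.ndarray  # s from record start
    rr: np.ndarray  # ms
    status: np.ndarray  # str per interval


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize_ecg(record: ECGRecord, mains_hz: float = 60.0,
                    baseline_window_s: float = 0.500) -> ECGRecord:
    """Resample to 500 Hz if slower, notch out mains, remove median baseline."""
    if record.fs < 100:
        raise ValueError(f"unsupported sampling rate {record.fs} Hz (minimum 100 Hz)")
    x = np.asarray(record.samples, dtype=float)
    fs = float(record.fs)
    if fs < TARGET_FS:
        n_out = int(round(len(x) * TARGET_FS / fs))
        t_in = np.arange(len(x)) / fs
        t_out = np.arange(n_out) / TARGET_FS
        spl = CubicSpline(t_in, x)
        x = spl(np.clip(t_out, 0, t_in[-1]))
        fs = TARGET_FS
    if mains_hz < fs / 2:
        b, a = iirnotch(mains_hz, Q=30.0, fs=fs)
        x = filtfilt(b, a, x)
    k = int(round(baseline_window_s * fs))
    if k % 2 == 0:
        k += 1
    baseline = median_filter(x, size=k, mode="nearest")
    return ECGRecord(samples=x - baseline, fs=fs,
                     start_time=record.start_time, lead=record.lead)


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def _peak_slope(x: np.ndarray, idx: int, fs: float, half_s: float = 0.050) -> float:
    h = int(round(half_s * fs))
    lo, hi = max(0, idx - h), min(len(x), idx + h + 1)
    if hi - lo < 2:
        return 0.0
    return float(np.abs(np.diff(x[lo:hi])).max() * fs)


def detect_r_peaks(record: ECGRecord, bandpass: tuple[float, float] = (5.0, 15.0),
                   integration_s: float = 0.150, threshold_frac: float = 0.12,
                   refine_s: float = 0.060) -> PeakList:
    """Pan-Tompkins-style QRS detection with a 250 ms refractory rule.

    Candidates come from the integrated squared derivative of the bandpassed
    signal against an adaptive (rolling-max) threshold, are refined to the
    local extremum of the raw trace, and whenever two survivors are closer
    than 250 ms the one with the larger maximal slope is retained.
    """
    x = np.asarray(record.samples, dtype=float)
    fs = float(record.fs)
    if len(x) < 2 * fs:
        raise ValueError("record shorter than 2 s")
    sos = butter(2, bandpass, btype="bandpass", fs=fs, output="sos")
    xf = sosfiltfilt(sos, x)
    der = np.gradient(xf) * fs
    sq = der**2
    integ = uniform_filter1d(sq, max(1, int(round(integration_s * fs))))
    gmax = integ.max()
    if gmax <= 0:
        return PeakList(indices=np.array([], dtype=int), slopes=np.array([]), fs=fs)
    roll = maximum_filter1d(integ, int(2 * fs))
    thr = np.maximum(threshold_frac * roll, 0.05 * gmax)
    cands, _ = find_peaks(integ, height=1e-12, distance=max(1, int(0.120 * fs)))
    cands = cands[integ[cands] >= thr[cands]]
    if len(cands) == 0:
        return PeakList(indices=np.array([], dtype=int), slopes=np.array([]), fs=fs)

    # refine to the raw-signal extremum (largest |x|) near each candidate
    h = int(round(refine_s * fs))
    refined = []
    for c in cands:
        lo, hi = max(0, c - h), min(len(x), c + h + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    refined = np.unique(refined)

    slopes = np.array([_peak_slope(x, i, fs) for i in refined])

    # refractory rule: while any adjacent pair is closer than 250 ms, drop
    # the shallower-slope member of the closest offending pair
    keep = list(range(len(refined)))
    min_gap = REFRACTORY_S * fs
    changed = True
    while changed and len(keep) > 1:
        changed = False
        for k in range(len(keep) - 1):
            i, j = keep[k], keep[k + 1]
            if refined[j] - refined[i] < min_gap:
                keep.pop(k if slopes[i] < slopes[j] else k + 1)
                changed = True
                break
    idx = refined[keep]
    return PeakList(indices=idx, slopes=slopes[keep], fs=fs)


# ---------------------------------------------------------------------------
# RR correction against the running 5-interval median
# ---------------------------------------------------------------------------

def _local_median(vals: list[float], i: int, half: int = 2) -> float:
    lo, hi = max(0, i - half), min(len(vals), i + half + 1)
    return float(np.median(vals[lo:hi]))


def correct_rr(peaks: PeakList, fs: float | None = None,
               short_frac: float = 0.5, long_frac: float = 2.0,
               merge_tol: float = 0.2) -> RRSeries:
    """Single left-to-right pass of the median-rule RR editing.

    At each interval the median m of the surrounding 5 (shrinking at the
    edges, recomputed on already-corrected values) is the expected RR.
    rr < short_frac·m with a neighbor summing back to within merge_tol·m of m
    ⇒ the shared peak was spurious: merge.  rr > long_frac·m ⇒ beats were
    missed: split into k = round(rr/m) equal intervals.
    """
    fs = fs or peaks.fs
    if len(peaks.indices) < 6:
        raise ValueError("need at least 6 peaks to correct RR")
    times = peaks.indices / fs
    rr = list(np.diff(times) * 1000.0)  # ms
    status = ["normal"] * len(rr)

    i = 0
    while i < len(rr):
        m = _local_median(rr, i)
        if rr[i] < short_frac * m:
            merged = False
            # try merging with whichever neighbor restores the median better
            cands = []
            if i + 1 < len(rr):
                cands.append((abs(rr[i] + rr[i + 1] - m), i + 1))
            if i - 1 >= 0:
                cands.append((abs(rr[i] + rr[i - 1] - m), i - 1))
            for dist, j in sorted(cands):
                if dist < merge_tol * m:
                    lo = min(i, j)
                    rr[lo:lo + 2] = [rr[i] + rr[j]]
                    status[lo:lo + 2] = ["removed-spurious-merge"]
                    i = lo  # re-examine the merged interval
                    merged = True
                    break
            if merged:
                continue
        elif rr[i] > long_frac * m:
            k = int(round(rr[i] / m))
            if k >= 2:
                piece = rr[i] / k
                rr[i:i + 1] = [piece] * k
                status[i:i + 1] = ["split-inserted"] * k
                i += k
                continue
        i += 1

    rr_arr = np.asarray(rr)
    beat_times = times[0] + np.concatenate([[0.0], np.cumsum(rr_arr)]) / 1000.0
    return RRSeries(beat_times=beat_times, rr=rr_arr,
                    status=np.asarray(status, dtype=object))
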