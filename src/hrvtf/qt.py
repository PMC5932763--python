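"""QT interval measurement and individualized rate correction.

T-wave end is located by the area method: within the search window after the
T peak, A(t) = Σ_{u=t-W}^{t} (x(u) - x(t)) peaks in magnitude where the wave
terminates (the subtracted-baseline area stops growing).  Each beat's QT is
then rate-corrected with a per-beat exponent from a local log-log regression
of QT on RR over the 41 temporally-nearest beats: QT = β·RR^α, and
QTc(i) = QT(i) / RR(i)^α(i) with RR in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ECGRecord, PeakList


@dataclass
class QTSeries:
    """Per-beat QT measurements and corrections (NaN where invalid)."""

    table: pd.DataFrame  # columns: q_onset, t_end, qt_ms, qtc_ms, alpha, valid


# ---------------------------------------------------------------------------
# QRS boundaries
# ---------------------------------------------------------------------------

def detect_qrs_boundaries(record: ECGRecord, peaks: PeakList,
                          window_s: float = 0.150, slope_frac: float = 0.02,
                          quiet_s: float = 0.012) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat (onset, offset) indices by slope-threshold crossing.

    Polarity is corrected per beat (the segment is flipped if the R deflection
    is negative).  Walking outward from the R peak, the complex ends at the
    first sustained quiet run (quiet_s of consecutive samples with |dV/dt|
    below slope_frac of the beat's maximal slope) — this keeps the P and T
    waves, whose slopes also exceed the threshold, out of the QRS.  Beats
    where no crossing is found are marked invalid with -1.
    """
    x = np.asarray(record.samples, dtype=float)
    fs = float(record.fs)
    h = int(round(window_s * fs))
    quiet = max(2, int(round(quiet_s * fs)))
    onsets = np.full(len(peaks.indices), -1, dtype=int)
    offsets = np.full(len(peaks.indices), -1, dtype=int)
    for k, i in enumerate(peaks.indices):
        lo, hi = max(0, i - h), min(len(x) - 1, i + h)
        seg = x[lo:hi + 1]
        if len(seg) < 5:
            continue
        if seg[i - lo] < 0:
            seg = -seg  # polarity correction
        d = np.abs(np.gradient(seg)) * fs
        dmax = d.max()
        if dmax <= 0:
            continue
        active = d > slope_frac * dmax
        p = i - lo
        # leftward walk: stop once `quiet` consecutive inactive samples seen
        onset = p
        run = 0
        for j in range(p, -1, -1):
            if active[j]:
                onset = j
                run = 0
            else:
                run += 1
                if run >= quiet:
                    break
        offset = p
        run = 0
        for j in range(p, len(seg)):
            if active[j]:
                offset = j
                run = 0
            else:
                run += 1
                if run >= quiet:
                    break
        if offset <= onset:
            continue
        onsets[k] = lo + onset
        offsets[k] = lo + offset
    return onsets, offsets


# ---------------------------------------------------------------------------
# T-wave end by the area method
# ---------------------------------------------------------------------------

def detect_t_end(record: ECGRecord, peaks: PeakList, qrs_offsets: np.ndarray,
                 area_window_s: float = 0.128, start_margin_s: float = 0.080,
                 end_margin_s: float = 0.020, noise_floor_mv: float = 0.05
                 ) -> np.ndarray:
    """Per-beat T-end index (-1 where invalid).

    Search window: (qrs_offset + start_margin, next QRS onset - end_margin)
    (record end for the last beat).  Within it, the T peak is the extremum of
    |x|; t_end = argmax over t > t_peak of s·A(t) with
    A(t) = Σ_{u=t-W}^{t} (x(u) - x(t)), W = area_window_s and s the sign of
    the T peak.  The sign correction makes the rule invariant to T-wave
    inversion while anchoring the maximum at the wave terminus (the unsigned
    |A| peaks on the steep flank right after the T peak instead).  Beats
    whose T amplitude is below noise_floor_mv are invalid.
    """
    x = np.asarray(record.samples, dtype=float)
    fs = float(record.fs)
    W = int(round(area_window_s * fs))
    cum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    idx = np.asarray(peaks.indices)
    t_ends = np.full(len(idx), -1, dtype=int)
    for k in range(len(idx)):
        if qrs_offsets[k] < 0:
            continue
        w_lo = qrs_offsets[k] + int(round(start_margin_s * fs))
        if k + 1 < len(idx):
            nxt = idx[k + 1] - int(round(0.045 * fs))  # approximate next onset
        else:
            nxt = n
        w_hi = min(n - 1, nxt - int(round(end_margin_s * fs)))
        if w_hi - w_lo < W // 2 or w_lo < W:
            continue
        seg = x[w_lo:w_hi + 1]
        p = int(np.argmax(np.abs(seg)))
        if np.abs(seg[p]) < noise_floor_mv:
            continue
        t_peak = w_lo + p
        cands = np.arange(t_peak + 1, w_hi + 1)
        if len(cands) == 0:
            continue
        # A(t) over the trailing window of W+1 samples ending at t
        area = (cum[cands + 1] - cum[cands - W]) - (W + 1) * x[cands]
        sign = 1.0 if seg[p] >= 0 else -1.0
        t_ends[k] = int(cands[np.argmax(sign * area)])
    return t_ends


# ---------------------------------------------------------------------------
# individualized QTc
# ---------------------------------------------------------------------------

def correct_qtc(qt_ms: np.ndarray, rr_s: np.ndarray, window: int = 41,
                valid: np.ndarray | None = None) -> pd.DataFrame:
    """Per-beat power-law rate correction QTc(i) = QT(i)/RR(i)^α(i).

    α(i) is the slope of the log QT ~ log RR regression over the `window`
    beats temporally nearest to i (a centered window, truncated at the record
    edges so it always spans exactly `window` valid beats).  Degenerate
    regressions (no RR spread) get α = NaN and QTc = QT.  Beats flagged
    invalid are excluded from every regression window and get NaN outputs.
    """
    qt_ms = np.asarray(qt_ms, dtype=float)
    rr_s = np.asarray(rr_s, dtype=float)
    n = len(qt_ms)
    if rr_s.shape != (n,):
        raise ValueError("qt and rr must have equal length")
    if valid is None:
        valid = np.isfinite(qt_ms) & np.isfinite(rr_s) & (qt_ms > 0) & (rr_s > 0)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(qt_ms) & np.isfinite(rr_s) \
            & (qt_ms > 0) & (rr_s > 0)
    vidx = np.flatnonzero(valid)
    nv = len(vidx)
    if nv < window:
        raise ValueError(f"need at least {window} valid beats")

    lx = np.log(rr_s[vidx])
    ly = np.log(qt_ms[vidx])
    # sliding-window regression over the valid subsequence via cumulative sums
    c1 = np.concatenate([[0.0], np.cumsum(lx)])
    c2 = np.concatenate([[0.0], np.cumsum(ly)])
    c3 = np.concatenate([[0.0], np.cumsum(lx * lx)])
    c4 = np.concatenate([[0.0], np.cumsum(lx * ly)])

    half = window // 2
    pos = np.arange(nv)
    starts = np.clip(pos - half, 0, nv - window)
    w = window
    sx = c1[starts + w] - c1[starts]
    sy = c2[starts + w] - c2[starts]
    sxx = c3[starts + w] - c3[starts]
    sxy = c4[starts + w] - c4[starts]
    denom = w * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_v = np.where(np.abs(denom) > 1e-12 * np.maximum(w * sxx, 1e-300),
                           (w * sxy - sx * sy) / denom, np.nan)

    alpha = np.full(n, np.nan)
    qtc = np.full(n, np.nan)
    alpha[vidx] = alpha_v
    a = np.where(np.isnan(alpha_v), 0.0, alpha_v)  # degenerate: QTc = QT
    qtc[vidx] = qt_ms[vidx] / rr_s[vidx] ** a

    return pd.DataFrame({
        "qt_ms": qt_ms, "qtc_ms": qtc, "alpha": alpha, "valid": valid,
        "alpha_degenerate": valid & np.isnan(alpha),
    })


def qt_pipeline(record: ECGRecord, peaks: PeakList, rr_s: np.ndarray | None = None,
                valid_beats: np.ndarray | None = None, window: int = 41) -> QTSeries:
    """QRS boundaries → T-end → QT → individualized QTc for one record."""
    onsets, offsets = detect_qrs_boundaries(record, peaks)
    t_ends = detect_t_end(record, peaks, offsets)
    fs = float(record.fs)
    qt_ms = np.where((t_ends > 0) & (onsets >= 0), (t_ends - onsets) / fs * 1000.0, np.nan)
    if rr_s is None:
        rr_s = np.full(len(peaks.indices), np.nan)
        rr_s[1:] = np.diff(peaks.indices) / fs
    ok = (t_ends > 0) & (onsets >= 0) & np.isfinite(rr_s)
    if valid_beats is not None:
        ok &= np.asarray(valid_beats, dtype=bool)
    tab = correct_qtc(qt_ms, rr_s, window=window, valid=ok)
    tab.insert(0, "t_end", t_ends)
    tab.insert(0, "q_onset", onsets)
    return QTSeries(table=tab)
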