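"""Hourly quantile series — the transform's actual input.

A multi-day beat stream is summarized one value per hour: the empirical
γ-quantile of the RR (or QTc) values in that hour.  Extreme quantiles
(γ = 0.01, 0.99) act as outlier-robust surrogates of the hourly minimum and
maximum heart rate; γ = 0.5 is the hourly median.  Hours with too few usable
beats carry an explicit missing marker and are linearly gap-filled (and
flagged) before the transform, which needs a gapless uniform series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class HourlySeries:
    """One value per hour with coverage bookkeeping.

    values holds NaN at hours whose coverage fell below the threshold;
    interpolated marks hours that were gap-filled by fill_gaps().
    """

    values: np.ndarray
    gamma: float
    source: str  # 'RR' | 'QTc' | 'invRR'
    coverage: np.ndarray
    interpolated: np.ndarray | None = None

    def hours(self) -> np.ndarray:
        return np.arange(len(self.values))


def hourly_quantile(beat_times_s: np.ndarray, values: np.ndarray, gamma: float,
                    source: str = "RR", min_coverage: float = 0.5,
                    excluded: np.ndarray | None = None) -> HourlySeries:
    """γ-quantile of the per-beat values within each hour bin [i·3600, (i+1)·3600).

    Quantiles use linear interpolation of order statistics; γ = 0 and γ = 1
    are the bin minimum and maximum.  Coverage is the beat count relative to
    the count expected from the record's overall median interval; hours below
    min_coverage are NaN.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    beat_times_s = np.asarray(beat_times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if beat_times_s.shape != values.shape:
        raise ValueError("beat_times and values must have equal length")
    if np.any(np.diff(beat_times_s) < 0):
        raise ValueError("beat_times must be sorted")
    usable = np.isfinite(values)
    if excluded is not None:
        usable &= ~np.asarray(excluded, dtype=bool)

    n_hours = int(np.ceil(beat_times_s[-1] / 3600.0)) if len(beat_times_s) else 0
    n_hours = max(n_hours, 1)
    out = np.full(n_hours, np.nan)
    cov = np.zeros(n_hours)

    dt = np.diff(beat_times_s)
    med_int = float(np.median(dt)) if len(dt) else np.nan
    expected = 3600.0 / med_int if med_int and np.isfinite(med_int) and med_int > 0 else np.nan

    hour = np.floor(beat_times_s / 3600.0).astype(int)
    hour = np.clip(hour, 0, n_hours - 1)
    for h in np.unique(hour[usable]):
        v = values[usable & (hour == h)]
        cov[h] = len(v) / expected if np.isfinite(expected) else 1.0
        if cov[h] >= min_coverage:
            out[h] = np.quantile(v, gamma, method="linear")
    return HourlySeries(values=out, gamma=gamma, source=source, coverage=cov)


def invert_series(series: HourlySeries) -> HourlySeries:
    """Elementwise 1000/RR: hourly beats-per-second; missing markers propagate."""
    v = series.values
    finite = np.isfinite(v)
    if np.any(v[finite] <= 0):
        raise ValueError("cannot invert non-positive values")
    out = np.where(finite, 1000.0 / v, np.nan)
    return HourlySeries(values=out, gamma=series.gamma, source="invRR",
                        coverage=series.coverage, interpolated=series.interpolated)


def fill_gaps(series: HourlySeries) -> HourlySeries:
    """Linear interpolation across missing hours, with flags.

    Leading/trailing gaps are filled by edge extension.  Raises if no hour is
    observed at all.
    """
    v = series.values.copy()
    ok = np.isfinite(v)
    if not ok.any():
        raise ValueError("series has no observed hours")
    hours = np.arange(len(v))
    filled = np.interp(hours, hours[ok], v[ok])
    return HourlySeries(values=filled, gamma=series.gamma, source=series.source,
                        coverage=series.coverage, interpolated=~ok)
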