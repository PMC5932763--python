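"""Dominant-ridge extraction and the non-rhythmic to rhythmic ratio (NRR).

The dominant oscillatory component of a tvPS traces a curve through the
time-frequency plane.  It is extracted as the path c(t) maximizing

    Σ_t log(tvPS[t, c(t)] + ε)  −  λ·Σ_t (c(t+1) − c(t))²

by dynamic programming (exact optimum).  The NRR function is, per time
column, the ratio of energy outside a band around the ridge to the energy
inside it; its standard deviation over time is the NRR index — a scalar
summary of how consistently the series is dominated by one rhythm (0 for a
perfectly concentrated, stationary-ridge spectrum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tf import TFRep

EPS = 1e-12


@dataclass
class Ridge:
    """One frequency bin per time column, with the ridge strength."""

    freq_bin: np.ndarray
    freq_value: np.ndarray
    strength: np.ndarray


@dataclass
class NRRResult:
    """Per-column NRR values and the scalar index."""

    nrr: np.ndarray  # NaN where the column was flagged
    nrr_index: float
    band_halfwidth: float
    valid: np.ndarray


def extract_dominant_ridge(tvps: TFRep, smoothness_penalty: float = 0.1,
                           eps: float = EPS) -> Ridge:
    """Exact maximum-score path through the tvPS by dynamic programming."""
    P = np.asarray(tvps.matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("tvPS must have at least 2 time columns")
    if np.all(P <= 0):
        raise ValueError("all-zero tvPS: no ridge to extract")
    T, F = P.shape
    logp = np.log(P + eps)
    bins = np.arange(F)
    penalty = smoothness_penalty * (bins[:, None] - bins[None, :]) ** 2  # (to, from)

    score = logp[0].copy()
    back = np.zeros((T, F), dtype=np.int32)
    for t in range(1, T):
        cand = score[None, :] - penalty  # (to, from)
        back[t] = np.argmax(cand, axis=1)
        score = cand[bins, back[t]] + logp[t]
    path = np.zeros(T, dtype=int)
    path[-1] = int(np.argmax(score))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return Ridge(freq_bin=path, freq_value=tvps.freq_grid[path],
                 strength=P[np.arange(T), path])


def ridge_score(tvps: TFRep, path: np.ndarray, smoothness_penalty: float = 1.0,
                eps: float = EPS) -> float:
    """Score of a candidate ridge path (used by the exhaustive oracle in tests)."""
    P = np.asarray(tvps.matrix, dtype=float)
    t = np.arange(P.shape[0])
    return float(np.sum(np.log(P[t, path] + eps))
                 - smoothness_penalty * np.sum(np.diff(path).astype(float) ** 2))


def nrr_function(tvps: TFRep, ridge: Ridge, band_halfwidth: float = 0.25) -> NRRResult:
    """Per-column E_out/E_in around the ridge, and the NRR index.

    The band is ±band_halfwidth in frequency units (cycles/day for hourly
    series).  Columns with zero in-band energy are flagged and excluded from
    the index, as are boundary-affected columns.  The index is the sample
    standard deviation (ddof=1) of the valid NRR values.
    """
    P = np.asarray(tvps.matrix, dtype=float)
    T, F = P.shape
    freq = tvps.freq_grid
    if band_halfwidth <= 0 or band_halfwidth >= (freq[-1] - freq[0]):
        raise ValueError("band_halfwidth must be positive and inside the grid span")
    in_band = np.abs(freq[None, :] - ridge.freq_value[:, None]) <= band_halfwidth
    e_in = np.where(in_band, P, 0.0).sum(axis=1)
    e_tot = P.sum(axis=1)
    e_out = e_tot - e_in
    valid = e_in > 0
    nrr = np.full(T, np.nan)
    nrr[valid] = e_out[valid] / e_in[valid]

    idx_valid = valid & tvps.interior()
    index = nrr_index(nrr[idx_valid])
    return NRRResult(nrr=nrr, nrr_index=index, band_halfwidth=band_halfwidth,
                     valid=idx_valid)


def nrr_index(nrr: np.ndarray) -> float:
    """Sample standard deviation of the valid NRR values."""
    v = np.asarray(nrr, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("need at least 2 valid NRR values")
    return float(np.std(v, ddof=1))
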