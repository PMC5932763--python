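"""ConceFT core: Hermite window bank, STFT, synchrosqueezing, multitaper averaging.

The transform chain is

1. build the first J Hermite windows (orthonormal on the discrete grid, with
   analytic derivative windows for the instantaneous-frequency estimate);
2. draw N random unit-norm linear combinations of the J windows;
3. for each combined window, compute the STFT and synchrosqueeze it — i.e.
   reassign each STFT coefficient along the frequency axis to the
   phase-derived instantaneous frequency ω̂(t,ω) = ω − Im(dV/V)·fs/(2π);
4. average the N squared-modulus reassigned spectra entrywise.

The result is the time-varying power spectrum (tvPS): a nonnegative
time × frequency matrix whose ridges trace the instantaneous frequencies of
the signal's oscillatory components.  Because the STFT is linear in the
window, the J base STFTs (and their derivative-window counterparts) are
computed once and the N combinations are formed in the STFT domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------

@dataclass
class ConceFTConfig:
    """Tunable parameters of the transform.

    half_width is half the window support in seconds (a "3.77 s window" has
    half_width 1.885).  The frequency axis is linear with n_freq_bins points
    on [freq_lo, freq_hi].  squeeze_threshold is relative to each column's
    maximum STFT modulus; coefficients below it are not reassigned.
    """

    J: int = 2
    N: int = 100
    half_width: float = 1.885
    freq_lo: float = 0.0
    freq_hi: float = 20.0
    n_freq_bins: int = 512
    hop: int = 1
    squeeze_threshold: float = 1e-6
    seed: int = 0

    def validate(self, fs: float) -> None:
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if not (0 <= self.freq_lo < self.freq_hi <= fs / 2):
            raise ValueError("require 0 <= freq_lo < freq_hi <= Nyquist")
        if not 0 < self.squeeze_threshold < 1:
            raise ValueError("squeeze_threshold must be in (0, 1)")
        if self.hop < 1:
            raise ValueError("hop must be >= 1")
        if self.n_freq_bins < 2:
            raise ValueError("need at least 2 frequency bins")

    def freq_grid(self) -> np.ndarray:
        return np.linspace(self.freq_lo, self.freq_hi, self.n_freq_bins)


@dataclass
class TFRep:
    """A time-frequency representation on explicit grids.

    matrix is time × frequency: complex for a raw STFT, real nonnegative for
    spectrogram / SST / tvPS.  boundary flags columns whose window overhangs
    the signal edges (zero-padded region).
    """

    time_grid: np.ndarray
    freq_grid: np.ndarray
    matrix: np.ndarray
    method: str
    config: ConceFTConfig | None = None
    boundary: np.ndarray | None = None
    fs: float | None = None

    def interior(self) -> np.ndarray:
        """Boolean mask of non-boundary columns."""
        if self.boundary is None:
            return np.ones(len(self.time_grid), dtype=bool)
        return ~self.boundary


@dataclass(frozen=True)
class WindowBank:
    """The first J Hermite windows, orthonormalized on the discrete grid.

    derivative_windows hold d w/d n (per-sample derivative), the quantity the
    synchrosqueezing reassignment formula needs.
    """

    windows: np.ndarray  # (J, L), unit-norm rows
    derivative_windows: np.ndarray  # (J, L)
    half_width: float  # s
    fs: float


@dataclass(frozen=True)
class CombinationScheme:
    """N random unit-norm vectors on the real J-sphere."""

    vectors: np.ndarray  # (N, J)
    seed: int


# ---------------------------------------------------------------------------
# Hermite windows
# ---------------------------------------------------------------------------

def hermite_window_bank(J: int, fs: float, half_width: float, tm: float = 6.0) -> WindowBank:
    """Sample the first J Hermite functions h_k(u) = H_k(u) e^{-u²/2} on
    u ∈ [-tm, tm] (L = 2·round(half_width·fs)+1 points), Löwdin-orthonormalize
    them on the discrete grid, and build the matching derivative windows.

    The derivative windows are the analytic derivatives
    h_k'(u) = (2k·H_{k-1}(u) − u·H_k(u))·e^{-u²/2}, combined with the same
    orthonormalizing transform and scaled by du so they are per-sample
    derivatives.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    half = int(round(half_width * fs))
    if half < J:
        raise ValueError("window too short for the requested number of Hermite functions")
    L = 2 * half + 1
    u = np.linspace(-tm, tm, L)
    du = u[1] - u[0]
    g = np.exp(-(u**2) / 2.0)

    # physicists' Hermite polynomials by recurrence
    H = np.zeros((J + 1, L))
    H[0] = 1.0
    if J >= 1:
        H[1] = 2.0 * u
    for k in range(2, J + 1):
        H[k] = 2.0 * u * H[k - 1] - 2.0 * (k - 1) * H[k - 2]

    psi = H[:J] * g  # (J, L)
    dpsi = np.zeros_like(psi)
    for k in range(J):
        dpsi[k] = (2.0 * k * (H[k - 1] if k >= 1 else 0.0) - u * H[k]) * g

    # per-row normalization first (keeps the Gram matrix well conditioned)
    norms = np.linalg.norm(psi, axis=1, keepdims=True)
    psi /= norms
    dpsi /= norms

    gram = psi @ psi.T
    # Löwdin symmetric orthonormalization: W = G^{-1/2} Psi
    evals, evecs = np.linalg.eigh(gram)
    if np.any(evals < 1e-12):
        raise ValueError("degenerate window bank: Hermite functions not resolvable on this grid")
    g_inv_sqrt = (evecs * (1.0 / np.sqrt(evals))) @ evecs.T
    windows = g_inv_sqrt @ psi
    dwindows = (g_inv_sqrt @ dpsi) * du  # per-sample derivative

    resid = np.abs(windows @ windows.T - np.eye(J)).max()
    if resid > 1e-6:
        raise ValueError(f"degenerate window bank: Gram residual {resid:.2e}")
    return WindowBank(windows=windows, derivative_windows=dwindows,
                      half_width=half_width, fs=fs)


# ---------------------------------------------------------------------------
# STFT
# ---------------------------------------------------------------------------

def _frames(signal: np.ndarray, L: int, hop: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Zero-padded frames of length L centered at samples 0, hop, 2·hop, …

    Returns (frames (T, L), center indices, boundary mask).
    """
    n = len(signal)
    half = (L - 1) // 2
    padded = np.concatenate([np.zeros(half), np.asarray(signal, dtype=float), np.zeros(half)])
    centers = np.arange(0, n, hop)
    idx = centers[:, None] + np.arange(L)[None, :]
    boundary = (centers < half) | (centers >= n - half)
    return padded[idx], centers, boundary


def _fourier_matrix(freqs: np.ndarray, L: int, fs: float) -> tuple[np.ndarray, np.ndarray]:
    offs = np.arange(L) - (L - 1) // 2
    arg = -2.0 * np.pi * np.outer(freqs, offs) / fs
    return np.cos(arg), np.sin(arg)


def _stft_frames(frames: np.ndarray, window: np.ndarray,
                 ere: np.ndarray, eim: np.ndarray) -> np.ndarray:
    xw = frames * window[None, :]
    return xw @ ere.T + 1j * (xw @ eim.T)


def stft(signal: np.ndarray, window: np.ndarray, config: ConceFTConfig,
         fs: float) -> TFRep:
    """V(t, ω) = Σ_s x[s]·w[s−t]·e^{−i2πω(s−t)/fs} on the configured grid."""
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    window = np.asarray(window, dtype=float)
    if signal.size < window.size:
        raise ValueError("signal shorter than the window")
    config.validate(fs)
    freqs = config.freq_grid()
    frames, centers, boundary = _frames(signal, len(window), config.hop)
    ere, eim = _fourier_matrix(freqs, len(window), fs)
    V = _stft_frames(frames, window, ere, eim)
    return TFRep(time_grid=centers / fs, freq_grid=freqs, matrix=V,
                 method="stft", config=config, boundary=boundary, fs=fs)


# ---------------------------------------------------------------------------
# synchrosqueezing
# ---------------------------------------------------------------------------

def _squeeze_matrix(V: np.ndarray, dV: np.ndarray, freqs: np.ndarray, fs: float,
                    threshold: float) -> np.ndarray:
    """Reassign complex STFT mass to the nearest instantaneous-frequency bin.

    Per column (time), coefficients with |V| above threshold·column-max are
    moved to the bin nearest ω̂ = ω − Im(dV/V)·fs/(2π); the output entry is
    the squared modulus of the complex sum received by each bin.  Mass
    reassigned outside the grid is dropped.
    """
    T, F = V.shape
    absV2 = V.real**2 + V.imag**2
    colmax = np.sqrt(absV2.max(axis=1, keepdims=True))
    mask = np.sqrt(absV2) > threshold * colmax
    out = np.zeros((T, F))
    if not mask.any():
        return out
    with np.errstate(divide="ignore", invalid="ignore"):
        im_ratio = (dV.imag * V.real - dV.real * V.imag) / absV2
    omega = freqs[None, :] - im_ratio * fs / (2.0 * np.pi)
    f0 = freqs[0]
    df = freqs[1] - freqs[0]
    bins = np.rint((omega - f0) / df)
    valid = mask & np.isfinite(bins) & (bins >= 0) & (bins < F)
    t_idx = np.broadcast_to(np.arange(T)[:, None], (T, F))[valid]
    flat = t_idx * F + bins[valid].astype(np.int64)
    vr = np.bincount(flat, weights=V.real[valid], minlength=T * F)
    vi = np.bincount(flat, weights=V.imag[valid], minlength=T * F)
    out = (vr * vr + vi * vi).reshape(T, F)
    return out


def synchrosqueeze(V: TFRep, dV: TFRep, config: ConceFTConfig | None = None) -> TFRep:
    """Synchrosqueeze a complex STFT given its derivative-window STFT."""
    if V.matrix.shape != dV.matrix.shape:
        raise ValueError("V and dV must have the same shape")
    cfg = config or V.config
    out = _squeeze_matrix(V.matrix, dV.matrix, V.freq_grid, V.fs,
                          cfg.squeeze_threshold)
    return TFRep(time_grid=V.time_grid, freq_grid=V.freq_grid, matrix=out,
                 method="sst", config=cfg, boundary=V.boundary, fs=V.fs)


def _base_stfts(signal: np.ndarray, bank: WindowBank, config: ConceFTConfig,
                fs: float) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray, np.ndarray, np.ndarray]:
    """STFTs of the signal under each base window and derivative window."""
    freqs = config.freq_grid()
    L = bank.windows.shape[1]
    frames, centers, boundary = _frames(np.asarray(signal, dtype=float), L, config.hop)
    ere, eim = _fourier_matrix(freqs, L, fs)
    Vs = [_stft_frames(frames, w, ere, eim) for w in bank.windows]
    dVs = [_stft_frames(frames, dw, ere, eim) for dw in bank.derivative_windows]
    return Vs, dVs, freqs, centers, boundary


def draw_combination_scheme(N: int, J: int, seed: int) -> CombinationScheme:
    """N unit-norm Gaussian vectors on the real J-sphere (seeded)."""
    rng = np.random.default_rng(seed)
    vecs = rng.standard_normal((N, J))
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    return CombinationScheme(vectors=vecs, seed=seed)


def _averaged_sst(signal: np.ndarray, config: ConceFTConfig, fs: float,
                  combos: np.ndarray, method: str) -> TFRep:
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    J = combos.shape[1]
    bank = hermite_window_bank(J, fs, config.half_width)
    if signal.size < bank.windows.shape[1]:
        raise ValueError("signal shorter than the window")
    Vs, dVs, freqs, centers, boundary = _base_stfts(signal, bank, config, fs)
    acc = np.zeros((len(centers), len(freqs)))
    for r in combos:
        if J == 1:
            Vc = r[0] * Vs[0]
            dVc = r[0] * dVs[0]
        else:
            Vc = sum(r[j] * Vs[j] for j in range(J))
            dVc = sum(r[j] * dVs[j] for j in range(J))
        acc += _squeeze_matrix(Vc, dVc, freqs, fs, config.squeeze_threshold)
    acc /= combos.shape[0]
    return TFRep(time_grid=centers / fs, freq_grid=freqs, matrix=acc,
                 method=method, config=config, boundary=boundary, fs=fs)


def conceft(signal: np.ndarray, config: ConceFTConfig, fs: float) -> TFRep:
    """The tvPS: average of N synchrosqueezed STFTs under random unit-norm
    combinations of the first J Hermite windows."""
    config.validate(fs)
    scheme = draw_combination_scheme(config.N, config.J, config.seed)
    return _averaged_sst(signal, config, fs, scheme.vectors, "conceft")


def mt_sst(signal: np.ndarray, J: int, config: ConceFTConfig, fs: float) -> TFRep:
    """Multitaper SST: average of the J single-Hermite-window synchrosqueezed
    STFTs (ConceFT with the identity combination scheme)."""
    cfg = replace(config, J=J, N=J)
    cfg.validate(fs)
    return _averaged_sst(signal, cfg, fs, np.eye(J), "mt-sst")


def sst(signal: np.ndarray, config: ConceFTConfig, fs: float) -> TFRep:
    """Single-window SST with the Hermite-0 (Gaussian) window."""
    cfg = replace(config, J=1, N=1)
    cfg.validate(fs)
    return _averaged_sst(signal, cfg, fs, np.eye(1), "sst")


# ---------------------------------------------------------------------------
# hourly-series convenience
# ---------------------------------------------------------------------------

#: samples per day for an hourly-sampled series; with this "sampling rate"
#: the frequency axis is in cycles/day (the circadian rhythm sits at 1.0).
HOURLY_FS_CPD = 24.0


def hourly_config(J: int = 3, N: int = 100, half_width_hours: float = 48.0,
                  freq_hi_cpd: float = 8.0, n_freq_bins: int = 256,
                  seed: int = 0) -> ConceFTConfig:
    """Transform configuration for hourly quantile series.

    The series is treated as sampled at 24 samples/day, so frequencies are in
    cycles/day.  The default window spans 4 days (half-width 48 hours = 2 days).
    """
    return ConceFTConfig(J=J, N=N, half_width=half_width_hours / HOURLY_FS_CPD,
                         freq_lo=0.0, freq_hi=freq_hi_cpd,
                         n_freq_bins=n_freq_bins, hop=1, seed=seed)


def conceft_hourly(values: np.ndarray, config: ConceFTConfig | None = None) -> TFRep:
    """ConceFT of an hourly series; time grid in days, frequencies in cycles/day."""
    cfg = config or hourly_config()
    rep = conceft(values, cfg, fs=HOURLY_FS_CPD)
    return rep
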