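"""Synthetic signals with known ground truth.

Three families of generators live here:

* the two-component AM-FM test signal whose amplitude and frequency paths are
  smoothed Brownian motions, contaminated by ARMA(1,1) noise with Student-t(4)
  innovations — the standard benchmark for sharpened time-frequency transforms;
* fixture-grade toy ECGs built from finite-support wave templates with exactly
  known R-peak, QRS-boundary and T-end positions, optionally with injected
  ectopic beats (premature beat + compensatory pause);
* long synthetic beat streams (RR-interval sequences) with a built-in circadian
  modulation, used to exercise the hourly-series / transform / summary chain at
  multi-day scale.

Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter


# ---------------------------------------------------------------------------
# smoothed Brownian paths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoothedBrownianPath:
    """A Gaussian random walk convolved with a Gaussian kernel, rescaled to a range."""

    values: np.ndarray
    n: int
    kernel_sd: float
    seed: int


def smoothed_brownian_path(
    n: int,
    step_sd: float = 1.0,
    kernel_sd: float = 1000.0,
    range_map: tuple[float, float] = (0.0, 1.0),
    seed: int = 0,
) -> SmoothedBrownianPath:
    """Cumulative-sum random walk, Gaussian-smoothed, affinely mapped into [lo, hi].

    ``step_sd == 0`` degenerates to the constant midpoint of the range.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if kernel_sd < 0:
        raise ValueError("kernel_sd must be nonnegative")
    lo, hi = range_map
    if not lo < hi:
        raise ValueError("range_map must satisfy lo < hi")
    rng = np.random.default_rng(seed)
    walk = np.cumsum(rng.normal(0.0, step_sd, size=n))
    if kernel_sd > 0:
        walk = gaussian_filter1d(walk, kernel_sd, mode="nearest")
    span = walk.max() - walk.min()
    if span == 0.0:
        values = np.full(n, 0.5 * (lo + hi))
    else:
        values = lo + (walk - walk.min()) * (hi - lo) / span
    return SmoothedBrownianPath(values=values, n=n, kernel_sd=kernel_sd, seed=seed)


# ---------------------------------------------------------------------------
# AM-FM components
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimComponent:
    """One AM-FM component A(t)·cos(φ(t)) alive on a finite support interval.

    ``amplitude`` already includes the support window (raised-cosine edge
    ramps), so the component samples are exactly zero outside ``support``.
    """

    amplitude: np.ndarray
    inst_freq: np.ndarray
    support: tuple[float, float]
    phase: np.ndarray
    samples: np.ndarray
    fs: float


def _support_window(t: np.ndarray, t0: float, t1: float, taper_s: float) -> np.ndarray:
    """1 inside [t0, t1], raised-cosine ramps of length taper_s at the edges, 0 outside."""
    w = np.zeros_like(t)
    inside = (t >= t0) & (t <= t1)
    w[inside] = 1.0
    if taper_s > 0:
        rise = inside & (t < t0 + taper_s)
        w[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - t0) / taper_s))
        fall = inside & (t > t1 - taper_s)
        w[fall] = 0.5 * (1 - np.cos(np.pi * (t1 - t[fall]) / taper_s))
    return w


def make_component(
    amp_path: SmoothedBrownianPath,
    freq_path: SmoothedBrownianPath,
    support: tuple[float, float],
    fs: float,
    taper_s: float = 1.0,
) -> SimComponent:
    """Assemble A(t)·cos(φ(t)) with φ the cumulative phase of the frequency path."""
    amp = np.asarray(amp_path.values, dtype=float)
    freq = np.asarray(freq_path.values, dtype=float)
    if amp.shape != freq.shape:
        raise ValueError("amplitude and frequency paths must have equal length")
    if np.any(freq <= 0) or np.any(freq >= fs / 2):
        raise ValueError("instantaneous frequency must lie strictly inside (0, Nyquist)")
    n = len(amp)
    t = np.arange(n) / fs
    t0, t1 = support
    if not (0.0 <= t0 < t1 <= t[-1] + 1.0 / fs):
        raise ValueError("support must lie within the signal duration")
    phase = 2.0 * np.pi * np.cumsum(freq) / fs
    win = _support_window(t, t0, t1, taper_s)
    amp_eff = amp * win
    samples = amp_eff * np.cos(phase)
    return SimComponent(
        amplitude=amp_eff, inst_freq=freq, support=(t0, t1), phase=phase,
        samples=samples, fs=fs,
    )


# ---------------------------------------------------------------------------
# ARMA(1,1) noise with Student-t innovations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ARMANoise:
    """ARMA noise a(B)X = b(B)ε with heavy-tailed Student-t innovations."""

    values: np.ndarray
    ar_poly: tuple[float, ...]
    ma_poly: tuple[float, ...]
    df: float
    seed: int


def arma_t4_noise(
    n: int,
    ar: tuple[float, ...] = (1.0, 0.5),
    ma: tuple[float, ...] = (1.0, -0.5),
    df: float = 4.0,
    seed: int = 0,
    burn_in: int = 1000,
) -> ARMANoise:
    """Simulate a(B)X = b(B)ε with ε i.i.d. Student-t(df).

    The polynomials are in the backshift operator B, constant term first:
    the defaults encode a(z) = 1 + 0.5 z and b(z) = 1 - 0.5 z.  A burn-in
    prefix is generated and discarded so the returned stretch is stationary.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    ar = tuple(float(c) for c in ar)
    ma = tuple(float(c) for c in ma)
    if ar[0] == 0:
        raise ValueError("AR polynomial must have nonzero constant term")
    if len(ar) > 1 and np.any(np.abs(np.roots(ar[::-1])) <= 1.0):
        raise ValueError("AR polynomial is not stable (root inside the unit disk)")
    rng = np.random.default_rng(seed)
    eps = rng.standard_t(df, size=n + burn_in)
    x = lfilter(ma, ar, eps)[burn_in:]
    return ARMANoise(values=x, ar_poly=ar, ma_poly=ma, df=df, seed=seed)


def arma11_lag1_acf(ar: tuple[float, ...] = (1.0, 0.5), ma: tuple[float, ...] = (1.0, -0.5)) -> float:
    """Closed-form lag-1 autocorrelation of the ARMA(1,1) process a(B)X = b(B)ε.

    With X_t = φX_{t-1} + ε_t + θε_{t-1} (so φ = -ar[1], θ = ma[1]):
    ρ₁ = (1+φθ)(φ+θ) / (1 + 2φθ + θ²).
    """
    phi, theta = -ar[1], ma[1]
    return (1 + phi * theta) * (phi + theta) / (1 + 2 * phi * theta + theta**2)


# ---------------------------------------------------------------------------
# assembled simulated signal
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimSignal:
    """Clean multi-component signal plus SNR-scaled noise, with full ground truth."""

    clean: np.ndarray
    noise: np.ndarray
    observed: np.ndarray
    fs: float
    snr_db: float
    truth: tuple[SimComponent, ...]


def assemble_sim_signal(
    components: list[SimComponent],
    noise: ARMANoise,
    target_snr_db: float = -2.0,
    fs: float = 100.0,
) -> SimSignal:
    """Sum the components and scale the noise to hit the target SNR exactly.

    SNR is the variance ratio: 10·log10(var(clean)/var(scaled noise)).  The
    scale factor is absolute, so any pre-scaling of the noise is immaterial.
    """
    if not np.isfinite(target_snr_db):
        raise ValueError("target SNR must be finite")
    clean = np.sum([c.samples for c in components], axis=0)
    if len(noise.values) != len(clean):
        raise ValueError("noise and components must have equal length")
    var_clean = float(np.var(clean))
    var_noise = float(np.var(noise.values))
    if var_clean == 0.0:
        raise ValueError("clean signal has zero variance")
    if var_noise == 0.0:
        raise ValueError("noise has zero variance")
    scale = np.sqrt(var_clean / (var_noise * 10.0 ** (target_snr_db / 10.0)))
    scaled = scale * noise.values
    realized = 10.0 * np.log10(var_clean / np.var(scaled))
    return SimSignal(
        clean=clean, noise=scaled, observed=clean + scaled, fs=fs,
        snr_db=float(realized), truth=tuple(components),
    )


def default_sim_signal(seed: int = 0, duration_s: float = 600.0, fs: float = 100.0,
                       target_snr_db: float = -2.0) -> SimSignal:
    """The benchmark two-component signal.

    Component 1: f ∈ [8, 12] Hz alive on [50, 450] s; component 2: f ∈ [2, 4] Hz
    alive on [150, 550] s; both amplitudes in [0.7, 1.3].  Amplitude/frequency
    paths are smoothed Brownian motions (10 s smoothing kernel), independent
    between components, and the noise is the default ARMA(1,1)-t(4) process
    scaled to the target SNR (-2 dB by default).
    """
    n = int(round(duration_s * fs))
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    kernel = 10.0 * fs  # 10 s smoothing
    a1 = smoothed_brownian_path(n, 1.0, kernel, (0.7, 1.3), seeds[0])
    f1 = smoothed_brownian_path(n, 1.0, kernel, (8.0, 12.0), seeds[1])
    a2 = smoothed_brownian_path(n, 1.0, kernel, (0.7, 1.3), seeds[2])
    f2 = smoothed_brownian_path(n, 1.0, kernel, (2.0, 4.0), seeds[3])
    sc = duration_s / 600.0  # supports scale with duration
    c1 = make_component(a1, f1, (50.0 * sc, 450.0 * sc), fs)
    c2 = make_component(a2, f2, (150.0 * sc, 550.0 * sc), fs)
    noise = arma_t4_noise(n, seed=seeds[4])
    return assemble_sim_signal([c1, c2], noise, target_snr_db=target_snr_db, fs=fs)


# ---------------------------------------------------------------------------
# toy ECG fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyECG:
    """Template-built ECG with exactly known fiducials for pipeline tests."""

    record: "ECGRecord"  # noqa: F821 - forward ref, resolved at import below
    true_r_peaks: np.ndarray
    true_t_ends: np.ndarray
    true_labels: np.ndarray  # True where ectopic
    true_qt: np.ndarray  # ms per beat
    true_rr: np.ndarray  # ms, len = n_beats - 1
    true_qrs_onsets: np.ndarray = field(default=None)
    true_qrs_offsets: np.ndarray = field(default=None)


def _bump(samples: np.ndarray, fs: float, center_s: float, half_s: float, amp: float) -> None:
    """Add a raised-cosine bump with exact finite support [center-half, center+half]."""
    i0 = max(0, int(np.ceil((center_s - half_s) * fs)))
    i1 = min(len(samples) - 1, int(np.floor((center_s + half_s) * fs)))
    if i1 < i0:
        return
    t = np.arange(i0, i1 + 1) / fs
    samples[i0:i1 + 1] += amp * 0.5 * (1 + np.cos(np.pi * (t - center_s) / half_s))


def synth_ecg(
    duration_s: float = 120.0,
    fs: float = 500.0,
    mean_rr: float = 800.0,
    rr_jitter: float = 0.0,
    ectopic_rate: float = 0.0,
    seed: int = 0,
    noise_mv: float = 0.0,
) -> ToyECG:
    """Piecewise template ECG: P-QRS-T per beat, with optional ectopic beats.

    Normal beat geometry (relative to the R peak, upright polarity):
    P at -160 ms (40 ms half-width), Q/R/S composing a QRS with exact support
    [-45, +45] ms, and a T wave supported on [+120, +280] ms.  The true QT
    (QRS onset to T end) is therefore 325 ms.  An ectopic beat is premature
    (0.6 of the local RR), has no P wave, a 1.6x taller and 1.5x wider QRS,
    and is followed by a compensatory pause restoring the two-beat sum to
    2·mean_rr.
    """
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz")
    if not 0 <= ectopic_rate < 0.5:
        raise ValueError("ectopic_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    samples = np.zeros(n)

    beat_times = []  # s
    labels = []  # ectopic flag
    t = 0.4  # leave room for the first beat's P wave
    pending_pause = False
    while t < duration_s - 0.4:
        beat_times.append(t)
        if pending_pause:
            labels.append(False)
            rr = 2 * mean_rr - 0.6 * mean_rr  # compensatory pause
            pending_pause = False
        else:
            base = mean_rr + (rng.normal(0.0, rr_jitter) if rr_jitter > 0 else 0.0)
            base = float(np.clip(base, 400.0, 2000.0))
            is_ectopic_next = len(beat_times) >= 3 and rng.random() < ectopic_rate
            if is_ectopic_next:
                rr = 0.6 * mean_rr
                pending_pause = True
            else:
                rr = base
            labels.append(False)
        t += rr / 1000.0

    # mark which beats are the ectopic ones: a beat is ectopic when the
    # interval *preceding* it is the premature one (0.6·mean_rr)
    beat_times = np.asarray(beat_times)
    labels = np.zeros(len(beat_times), dtype=bool)
    rr_ms = np.diff(beat_times) * 1000.0
    for i in range(1, len(beat_times)):
        if abs(rr_ms[i - 1] - 0.6 * mean_rr) < 1e-6:
            labels[i] = True

    qrs_half = 0.045  # QRS support [-45, +45] ms
    t_end_off = 0.280
    onsets, offsets, t_ends, qts = [], [], [], []
    for bt, ect in zip(beat_times, labels):
        w = 1.5 if ect else 1.0
        a = 1.6 if ect else 1.0
        if not ect:
            _bump(samples, fs, bt - 0.160, 0.040, 0.12)  # P
        _bump(samples, fs, bt - 0.030 * w, 0.015 * w, -0.12 * a)  # Q
        _bump(samples, fs, bt, 0.022 * w, 1.0 * a)  # R
        _bump(samples, fs, bt + 0.030 * w, 0.015 * w, -0.20 * a)  # S
        _bump(samples, fs, bt + 0.200, 0.080, 0.30)  # T
        onsets.append(int(round((bt - qrs_half * w) * fs)))
        offsets.append(int(round((bt + qrs_half * w) * fs)))
        t_ends.append(int(round((bt + t_end_off) * fs)))
        qts.append((t_end_off + qrs_half * w) * 1000.0)

    if noise_mv > 0:
        samples = samples + rng.normal(0.0, noise_mv, size=n)

    from .preprocess import ECGRecord

    rec = ECGRecord(samples=samples, fs=fs, start_time=0.0, lead="synthetic")
    return ToyECG(
        record=rec,
        true_r_peaks=np.round(beat_times * fs).astype(int),
        true_t_ends=np.asarray(t_ends, dtype=int),
        true_labels=labels,
        true_qt=np.asarray(qts),
        true_rr=rr_ms,
        true_qrs_onsets=np.asarray(onsets, dtype=int),
        true_qrs_offsets=np.asarray(offsets, dtype=int),
    )


# ---------------------------------------------------------------------------
# long synthetic beat streams
# ---------------------------------------------------------------------------

def synth_beat_stream(
    duration_h: float = 325.0,
    mean_rr: float = 900.0,
    circadian_amp: float = 100.0,
    jitter: float = 20.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """RR-interval stream with a 24 h modulation.

    Returns (beat_times_s, rr_ms) where rr_ms[i] is the interval ending at
    beat_times_s[i+1].  rr(t) = mean_rr + circadian_amp·sin(2πt/86400) + noise.
    """
    rng = np.random.default_rng(seed)
    dur_s = duration_h * 3600.0
    # upper bound on beat count, then trim
    n_max = int(dur_s / ((mean_rr - circadian_amp) / 1000.0)) + 10
    times = [0.0]
    t = 0.0
    # vectorized batches to keep this fast for ~1e6 beats
    while t < dur_s:
        batch = 100000
        base = mean_rr + circadian_amp * np.sin(2 * np.pi * (t + np.arange(batch) * mean_rr / 1000.0) / 86400.0)
        rr = base + rng.normal(0.0, jitter, size=batch)
        rr = np.clip(rr, 300.0, 3000.0) / 1000.0
        cum = t + np.cumsum(rr)
        keep = cum < dur_s
        times.extend(cum[keep].tolist())
        if not keep.all():
            break
        t = cum[-1]
    beat_times = np.asarray(times)
    rr_ms = np.diff(beat_times) * 1000.0
    return beat_times, rr_ms
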