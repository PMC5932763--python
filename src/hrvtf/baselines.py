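"""Linear-type reference transforms and the sharpness comparison harness.

The spectrogram (squared-modulus STFT) and scalogram (squared-modulus CWT)
are the classical linear time-frequency representations that the sharpened
tvPS is compared against: both smear an oscillatory component's ridge over
the window/wavelet bandwidth, while synchrosqueezing concentrates it.
"""

from __future__ import annotations

import numpy as np
import pywt

from .tf import ConceFTConfig, TFRep, conceft, hermite_window_bank, mt_sst, stft


def spectrogram(signal: np.ndarray, window: np.ndarray, config: ConceFTConfig,
                fs: float) -> TFRep:
    """|STFT|² on the configured grids."""
    rep = stft(signal, window, config, fs)
    mat = rep.matrix.real**2 + rep.matrix.imag**2
    return TFRep(time_grid=rep.time_grid, freq_grid=rep.freq_grid, matrix=mat,
                 method="spectrogram", config=config, boundary=rep.boundary, fs=fs)


def scalogram(signal: np.ndarray, fs: float, config: ConceFTConfig,
              wavelet_center_freq: float = 1.0, n_voices: int = 16,
              bandwidth: float = 1.0) -> TFRep:
    """Squared-modulus CWT with an analytic complex Morlet wavelet.

    Scales are log-spaced at n_voices per octave and mapped to a frequency
    axis via the wavelet center frequency; the frequency range is
    [max(freq_lo, freq_hi/64), freq_hi] so scales stay finite.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    f_hi = config.freq_hi
    f_lo = max(config.freq_lo, f_hi / 64.0)
    n_octaves = np.log2(f_hi / f_lo)
    n_scales = int(np.ceil(n_octaves * n_voices)) + 1
    freqs = np.geomspace(f_lo, f_hi, n_scales)
    wav = pywt.ContinuousWavelet(f"cmor{bandwidth}-{wavelet_center_freq}")
    scales = wavelet_center_freq * fs / freqs
    if scales.max() > signal.size:
        raise ValueError("largest wavelet scale exceeds the signal length")
    coef, out_freqs = pywt.cwt(signal, scales, wav, sampling_period=1.0 / fs)
    # coef: (n_scales, n_samples); subsample in time by the configured hop
    centers = np.arange(0, signal.size, config.hop)
    power = np.abs(coef[:, centers]) ** 2  # (F, T)
    order = np.argsort(out_freqs)
    power = power[order].T  # time x frequency, ascending frequency
    out_freqs = out_freqs[order]
    # boundary: columns within the largest wavelet support of the edges
    half = int(scales.max() / 2)
    boundary = (centers < half) | (centers >= signal.size - half)
    return TFRep(time_grid=centers / fs, freq_grid=out_freqs, matrix=power,
                 method="scalogram", config=config, boundary=boundary, fs=fs)


# ---------------------------------------------------------------------------
# sharpness comparison harness
# ---------------------------------------------------------------------------

def ridge_energy_fraction(rep: TFRep, truth_freqs: list[np.ndarray],
                          truth_active: list[np.ndarray], band_hz: float) -> float:
    """Fraction of total TF energy within ±band_hz of the true IF curves.

    truth_freqs[c][t] is component c's instantaneous frequency at the time of
    column t of rep (NaN or truth_active[c][t] False when the component is
    off).  Columns where no component is active, and boundary columns, are
    excluded from both numerator and denominator.
    """
    P = rep.matrix
    T = P.shape[0]
    near = np.zeros((T, P.shape[1]), dtype=bool)
    any_active = np.zeros(T, dtype=bool)
    for fc, act in zip(truth_freqs, truth_active):
        act = act & np.isfinite(fc)
        any_active |= act
        d = np.abs(rep.freq_grid[None, :] - fc[:, None])
        near |= act[:, None] & (d <= band_hz)
    cols = any_active & rep.interior()
    total = P[cols].sum()
    if total <= 0:
        return 0.0
    return float(P[cols][near[cols]].sum() / total)


def _truth_at_columns(sim, rep: TFRep) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Sample each true component's IF path at the transform's column times."""
    idx = np.clip(np.round(rep.time_grid * sim.fs).astype(int), 0,
                  len(sim.observed) - 1)
    freqs, actives = [], []
    for comp in sim.truth:
        t = rep.time_grid
        t0, t1 = comp.support
        active = (t >= t0) & (t <= t1)
        freqs.append(comp.inst_freq[idx])
        actives.append(active)
    return freqs, actives


def sharpness_comparison(sim, config: ConceFTConfig, band_bins: int = 3,
                         mt_J: int = 6) -> dict[str, float]:
    """Ridge-energy concentration of ConceFT vs MT-SST vs spectrogram vs scalogram.

    All methods run on the same signal with the same window half-width; the
    concentration band is ±band_bins grid steps of the common linear grid,
    expressed in Hz so the log-spaced scalogram grid is scored on equal terms.
    """
    x = sim.observed
    fs = sim.fs
    df = (config.freq_hi - config.freq_lo) / (config.n_freq_bins - 1)
    band_hz = band_bins * df

    reps = {
        "conceft": conceft(x, config, fs),
        "mt_sst": mt_sst(x, mt_J, config, fs),
    }
    bank = hermite_window_bank(1, fs, config.half_width)
    reps["spectrogram"] = spectrogram(x, bank.windows[0], config, fs)
    reps["scalogram"] = scalogram(x, fs, config)

    out = {}
    for name, rep in reps.items():
        tf_truth, tf_active = _truth_at_columns(sim, rep)
        out[name] = ridge_energy_fraction(rep, tf_truth, tf_active, band_hz)
    return out
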