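# hrvtf — time-frequency HRV and QT variability for multi-day ECG

`hrvtf` analyzes heart-rate variability (HRV) and QT variability in
extra-long-term (up to ~2 week) single-lead ECG recordings. Classical HRV
indices assume stationarity that multi-day signals do not have; this package
instead summarizes the recording as hourly quantile series of the RR and
rate-corrected QT (QTc) intervals and applies a sharpened, noise-stabilized
nonlinear time-frequency transform — the concentration of frequency and time
(ConceFT) — to expose slow rhythms (e.g. the circadian oscillation at
1 cycle/day) as crisp curves in a time-varying power spectrum (tvPS).

It is intended for physiological signal-processing researchers working with
patch/Holter monitor data who need interpretable spectral dynamics from
noisy, nonstationary interval series.

## Method

For a window w and its derivative window w′, the STFT is
V(t,ω) = Σ_s x[s]·w[s−t]·e^{−i2πω(s−t)/fs}. Synchrosqueezing reassigns each
coefficient along frequency to ω̂(t,ω) = ω − Im(V_{w′}/V_w)·fs/(2π),
collapsing each oscillatory component onto its instantaneous-frequency
curve. ConceFT averages the synchrosqueezed power over N random unit-norm
linear combinations of the first J Hermite windows — a nonlinear multitaper
that keeps the sharpness of synchrosqueezing while suppressing noise.

Around the transform sits a complete ECG chain:

* standardization (500 Hz resampling, mains notch, 500 ms median baseline);
* Pan–Tompkins-style R-peak detection with a 250 ms refractory rule keeping
  the steeper-slope peak;
* RR correction against a running 5-interval median (0.5× merge / 2× split
  with k = round(rr/m));
* SVM beat classification (6 features) with 10-min/80% segment exclusion and
  nonlinear predictive interpolation of ectopic + compensatory-pause
  intervals;
* T-end detection by the area method and per-beat individualized
  QTc(i) = QT(i)/RR(i)^α(i), α from a local 41-beat log-log fit of
  QT = β·RR^α;
* hourly γ-quantile series (γ ∈ {0.01, 0.5, 0.99});
* dominant-ridge extraction by dynamic programming and the NRR index — the
  standard deviation over time of the non-rhythmic to rhythmic energy ratio
  around the ridge.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Generate the benchmark signal (two AM–FM components with time-varying
amplitude and frequency, ARMA(1,1) Student-t4 noise at −2 dB SNR) and compare
how much time-frequency energy each method keeps within ±3 bins of the true
instantaneous frequencies:

```python
from hrvtf import default_sim_signal
from hrvtf.baselines import sharpness_comparison
from hrvtf.tf import ConceFTConfig

sim = default_sim_signal(seed=0)          # 600 s at 100 Hz, SNR -2 dB
print(round(sim.snr_db, 3))               # -2.0
cfg = ConceFTConfig(J=2, N=100, half_width=1.885, freq_lo=0.0, freq_hi=20.0,
                    n_freq_bins=512, hop=50, seed=0)
for name, frac in sharpness_comparison(sim, cfg).items():
    print(f"{name:12s} {100*frac:5.1f}%")
```

prints

```
conceft       98.2%
mt_sst        93.2%
spectrogram   24.2%
scalogram     15.2%
```

— ConceFT concentrates ~98% of the spectral energy on the true
instantaneous-frequency curves, the plain multitaper synchrosqueezed
spectrogram ~93%, while the linear methods smear three quarters of it away.

A multi-day interval stream goes through the hourly chain:

```python
from hrvtf import synth_beat_stream, hourly_quantile, fill_gaps
from hrvtf.tf import conceft, hourly_config, HOURLY_FS_CPD
from hrvtf.ridge import extract_dominant_ridge, nrr_function
import numpy as np

bt, rr = synth_beat_stream(duration_h=325, seed=3)   # circadian RR stream
hs = fill_gaps(hourly_quantile(bt[1:], rr, gamma=0.5))
rep = conceft(hs.values - hs.values.mean(), hourly_config(seed=3),
              fs=HOURLY_FS_CPD)
ridge = extract_dominant_ridge(rep)
print(round(float(np.median(ridge.freq_value[rep.interior()])), 3))  # 1.004
print(round(nrr_function(rep, ridge).nrr_index, 4))                  # 0.0051
```

The dominant tvPS ridge sits at 1.004 cycles/day — the built-in 24 h
modulation — and the small NRR index says the spectrum stays concentrated
around that single rhythm.

The same stages are scriptable from the shell: `hrvtf simulate`, `hrvtf
preprocess`, `hrvtf qt`, `hrvtf series`, `hrvtf tvps`, `hrvtf nrr`,
`hrvtf compare`, `hrvtf render`, and `hrvtf run` (the full pipeline on an
ECG CSV).

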