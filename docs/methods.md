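# Methods

## Problem and approach

Multi-day ("extra-long-term") single-lead ECG recordings — two weeks of
continuous signal from an adhesive patch monitor — contain slow rhythms that
24–48 h heart-rate-variability (HRV) methods, built on stationarity
assumptions, cannot resolve. This package analyzes such recordings with a
nonlinear time–frequency transform, the concentration of frequency and time
(ConceFT), applied to hourly quantile summaries of the beat-to-beat RR and
rate-corrected QT (QTc) interval streams. The output is a time-varying power
spectrum (tvPS) whose ridges reveal, e.g., a circadian oscillation as a curve
at 1 cycle/day, and a scalar summary, the non-rhythmic to rhythmic ratio
(NRR) index.

The chain is: ECG standardization → R-peak detection → RR correction →
arrhythmic-beat editing → QT/QTc measurement → hourly γ-quantile series →
ConceFT tvPS → dominant ridge → NRR.

## The transform

The short-time Fourier transform (STFT) with window w is
V(t, ω) = Σ_s x[s] w[s−t] e^{−i2πω(s−t)/fs}. Its squared modulus (the
spectrogram) smears each oscillatory component over the window bandwidth —
the uncertainty-principle blur of every linear time-frequency method.
Synchrosqueezing (SST) undoes the smear along the frequency axis: with the
derivative-window STFT dV, the instantaneous-frequency estimate at (t, ω) is
ω̂ = ω − Im(dV/V)·fs/(2π), and each coefficient's complex mass is reassigned
to the bin nearest ω̂; each output entry is the squared modulus of the mass
it received. Coefficients below a relative threshold (default 1e−6 of the
column maximum) are discarded before reassignment, so numerical noise in
near-zero coefficients cannot be reassigned anywhere.

ConceFT stabilizes the sharpened spectrum against noise: take the first J
Hermite functions (the optimally time-frequency-concentrated orthonormal
family), draw N random unit-norm linear combinations r ∈ S^{J−1}, compute the
SST under each combined window, and average the N nonnegative outputs.
Because the STFT is linear in the window, the J base STFTs (and their
derivative counterparts) are computed once and the N combinations are formed
in the transform domain — the cost is J·2 STFTs plus N reassignment passes,
not N·2 STFTs.

Design choices where the construction is genuinely open:

* **Real combination sphere.** Combinations are real unit vectors (normalized
  Gaussians); complex spheres are equally valid and the literature uses both.
  Seeded, so the tvPS is a pure function of (signal, config, seed).
* **Power averaging.** The N synchrosqueezed outputs are averaged as squared
  moduli, so the tvPS carries power-spectrum units.
* **Windows.** Hermite functions are sampled on u ∈ [−6, 6] over
  L = 2·round(half_width·fs)+1 points and Löwdin-orthonormalized on the
  discrete grid (the correction to the analytic functions is ≤1e−10 for
  J ≤ 10); derivative windows are the analytic derivatives under the same
  transform, scaled to per-sample units. `half_width` is half the window
  support: a "3.77 s window" has half_width 1.885 s.
* **Grids and boundaries.** Linear frequency grid (default 512 bins);
  reassigned mass falling off-grid is dropped. Signals are zero-padded at the
  edges and the first/last half-window of columns are flagged
  boundary-affected; summary statistics exclude them.
* **Hourly convention.** An hourly series is treated as sampled at 24
  samples/day, making the frequency axis cycles/day: the circadian rhythm
  sits at 1.0. Default analysis window 2 days half-width, J = 3, N = 100.

The multitaper SST (`mt_sst`) is the same machinery with the identity
combination scheme (plain average over the J Hermite windows), and
`conceft(J=1, N=1)` reduces bitwise to the single-window SST.

## ECG preprocessing

Records slower than 500 Hz are cubic-spline upsampled to 500 Hz; mains
interference is removed with a notch filter (Q = 30) and baseline wander by
subtracting a 500 ms running median. R peaks come from a Pan–Tompkins-style
detector (5–15 Hz bandpass, squared derivative, 150 ms integration, adaptive
rolling-maximum threshold at 12% with a 5%-of-global floor), refined to the
raw-signal extremum; when two detections fall within the 250 ms refractory
period the one with the larger maximal |dV/dt| survives.

RR correction runs a single left-to-right pass against the median of the
five surrounding intervals (recomputed on already-corrected values, shrinking
at the edges): an interval under 0.5× the median whose sum with a neighbor is
within 0.2× of the median marks a spurious peak (merge); an interval over 2×
the median marks missed beats and is split into k = round(rr/median) equal
parts. The 0.2 merge tolerance is a package choice; the 0.5×/2× criteria and
the 5-interval median are fixed by the method.

## Arrhythmic-beat editing

Six per-beat features feed an RBF-SVM (standardized features, C = 10,
balanced class weights): R amplitude, previous and next RR, trailing 10-beat
mean RR, beat phase, and QRS duration. "Phase" is implemented as the beat's
prematurity, dt_prev / mean_rr10 wrapped to [0, 1) — a premature ectopic sits
near 0.6 while sinus beats sit near 0 (≡1). Edge beats without a full
history carry explicit NaN markers and are never silently dropped. When no
trained classifier is supplied the pipeline falls back to a rhythm rule
(interval deviating >20% from the local 11-interval median).

Ten-minute segments with under 80% normal beats (strict inequality) are
excluded wholesale; the remaining abnormal intervals — the ectopic and its
compensatory pause, each flagged — are replaced by nonlinear predictive
interpolation: the query is the 10 intervals preceding the gap (corrected
values, causal left-to-right), the templates are all runs of 10 consecutive
originally-normal intervals with a normal follower that do not overlap the
query, and the replacement is the follower of the Euclidean-nearest template
(ties to the earliest start). Replacements are therefore always values the
record actually contains.

## QT and individualized QTc

QRS boundaries are found per beat after polarity correction by walking
outward from the R peak until |dV/dt| stays below 2% of the beat's maximal
slope for 12 ms — the sustained-quiet rule keeps the P and T waves, whose
slopes also cross the threshold, out of the complex. T-wave end uses the
area method: A(t) = Σ_{u=t−W}^{t} (x(u) − x(t)) with W = 128 ms, searched in
(QRS offset + 80 ms, next onset − 20 ms); t_end is the argmax of sign(T)·A
after the T peak. The sign correction keeps the rule invariant to T-wave
inversion while anchoring the maximum at the wave terminus — the unsigned
|A| peaks on the steep flank just after the T peak, where the −(W+1)·x(t)
term dominates, and calls the end ~80 ms early on fixtures. Beats with T
amplitude under 0.05 mV are flagged invalid.

Each beat's QT is rate-corrected with a per-beat exponent: over the 41
temporally nearest valid beats (centered window, truncated to exactly 41 at
record edges, index beat included), regress log QT on log RR (RR in
seconds); α is the slope and QTc(i) = QT(i)/RR(i)^α(i). Windows with no RR
spread get α = NaN, QTc = QT, and an `alpha_degenerate` flag.

## Hourly series

R_hour,γ(i) is the γ-quantile (linear interpolation of order statistics,
γ = 0 min, γ = 1 max) of the usable RR values in hour i; Q_hour,γ likewise
for QTc, and 1000/RR gives the inverse (beats/s) series. Defaults are
γ ∈ {0.01, 0.5, 0.99}: the extreme quantiles are outlier-robust surrogates of
the hourly minimum and maximum heart rate. Hours with fewer than 50% of the
expected beat count (expected = 3600 s / overall median interval) are marked
missing; before the transform, gaps are filled by linear interpolation and
flagged, since synchrosqueezing needs a gapless uniform series.

## Ridge and NRR

The dominant ridge maximizes Σ_t log(tvPS[t, c(t)] + ε) − λ·Σ_t Δc(t)² over
paths c by dynamic programming (exact optimum; ε = 1e−12). λ defaults to
0.1 per squared bin: on the default grids the true ridge of a drifting
component moves more than one bin per column, and a unit penalty then
overwhelms the log-power contrast between components, pulling the path onto
a flatter but weaker ridge; 0.1 tracks drifting ridges while still
suppressing single-column outliers. λ should scale down as the grid gets
finer or the hop longer.

The NRR function is E_out/E_in per column, where E_in is the tvPS energy
within ±0.25 cycles/day of the ridge (configurable; the orientation is
non-rhythmic over rhythmic, so perfectly concentrated spectra give 0). The
NRR index is the sample standard deviation (ddof = 1) of the NRR over valid,
non-boundary columns. Both are invariant to rescaling the tvPS.

## Simulated signals

The transform benchmark is a two-component AM–FM signal: amplitude and
frequency paths are smoothed Brownian motions (Gaussian random walk,
Gaussian smoothing kernel of 10 s, affinely mapped into range), component 1
with f ∈ [8, 12] Hz alive on [50, 450] s and component 2 with f ∈ [2, 4] Hz
on [150, 550] s of a 600 s record at 100 Hz, amplitudes in [0.7, 1.3].
Finite supports carry a 1 s raised-cosine edge ramp (configurable to 0) to
avoid transform ringing from jump discontinuities. Noise is ARMA(1,1),
a(B)X = b(B)ε with a(z) = 1 + 0.5z, b(z) = 1 − 0.5z, i.i.d. Student-t(4)
innovations (heavy tails mimicking spurious/missed-beat artifacts), 1000
samples of burn-in discarded; its theoretical lag-1 autocorrelation is
−5/7 ≈ −0.714. The noise is scaled by a single factor so that the variance
ratio realizes the target SNR (−2 dB default) exactly; innovations are not
variance-normalized beforehand since the scaling makes that immaterial. The
two components use independent randomness (spawned sub-seeds).

The toy ECG is fixture-grade, not physiological: each beat is a sum of
raised-cosine bumps with exact finite support (P at −160 ms; Q/R/S composing
a QRS supported exactly on ±45 ms; T supported on [120, 280] ms, so true
QT = 325 ms). Ectopic beats are premature (0.6× the local RR), P-less, with
a 1.6× taller and 1.5× wider QRS and a compensatory pause restoring the
two-beat sum. Because supports and fiducials are exact, detector errors are
measured against ground truth rather than against another algorithm. What
passing these tests does **not** show: robustness to real muscle/motion
artifact, electrode noise, morphology drift, or genuine arrhythmia — the
fixtures have clean template morphology by construction.

The multi-day fixture is a beat stream (no waveform): RR(t) = 900 ms +
100 ms·sin(2πt/86400) + N(0, 20 ms), i.e. a circadian modulation that the
hourly series → tvPS → ridge chain must place at 1 cycle/day.

## Problem sizes and numerical notes

The transform comparison uses the 600 s / 100 Hz benchmark signal with a
0.5 s hop (1200 columns, 512 bins), J = 2, N = 100 against MT-SST (J = 6,
same 3.77 s window), the spectrogram, and a complex-Morlet scalogram (16
voices/octave); concentration is the fraction of time-frequency energy
within ±3 linear-grid bins (±0.117 Hz) of the true instantaneous
frequencies, over interior columns where a component is active, the band
expressed in Hz so the log-spaced scalogram grid is scored on equal terms.
Editing and QT tests run on 1–3 h toy records at 200–500 Hz; the circadian
analysis uses a 325 h stream (~1.3 M beats). The full default test suite
runs in about 3 minutes on one CPU.

Ties in the ridge DP and template search break toward the lower bin /
earlier start for determinism. All RNG flows through
`numpy.random.default_rng` with explicit seeds; sub-seeds are spawned via
`SeedSequence` and kept below 2³¹.

## Known limitations

* WFDB I/O is not provided; records enter as two-column CSV (time_s, mv).
  The beat classifier trains on user-supplied feature/label arrays — there
  is no bundled arrhythmia-database model.
* The tvPS is not invertible here: no reconstruction, no second-order
  synchrosqueezing, and no Cohen-class transforms.
* Only binary sinus/abnormal beat labels; no rhythm-episode (e.g. AF)
  detection.
* The NRR index summarizes concentration around a single dominant ridge;
  multi-ridge spectra are reduced to the strongest path.
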