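"""Transform core: Hermite windows, STFT, synchrosqueezing, ConceFT/MT-SST."""

import numpy as np
import pytest

from hrvtf import default_sim_signal
from hrvtf.tf import (ConceFTConfig, conceft, hermite_window_bank, mt_sst, sst,
                      stft, synchrosqueeze)

from conftest import tone


class TestHermiteWindows:
    def test_single_window_is_symmetric_gaussian(self):
        b = hermite_window_bank(1, 100.0, 1.0)
        w = b.windows[0]
        assert np.allclose(w, w[::-1], atol=1e-12)
        assert np.argmax(w) == len(w) // 2
        assert np.all(w > 0)

    @pytest.mark.parametrize("J", [3, 6, 10])
    def test_orthonormality(self, J):
        b = hermite_window_bank(J, 100.0, 2.0)
        gram = b.windows @ b.windows.T
        assert np.abs(gram - np.eye(J)).max() < 1e-8

    def test_matches_gram_schmidt_oracle(self):
        """Löwdin-orthonormalized Hermite functions equal Gram-Schmidt
        orthonormalization of {u^k exp(-u²/2)} on the same grid, up to sign."""
        J, fs, hw, tm = 6, 100.0, 1.885, 6.0
        b = hermite_window_bank(J, fs, hw, tm=tm)
        L = b.windows.shape[1]
        u = np.linspace(-tm, tm, L)
        basis = np.array([u**k * np.exp(-u**2 / 2) for k in range(J)])
        ortho = []
        for v in basis:  # classical Gram-Schmidt
            w = v.copy()
            for q in ortho:
                w = w - (q @ w) * q
            ortho.append(w / np.linalg.norm(w))
        oracle = np.array(ortho)
        for j in range(J):
            s = np.sign(oracle[j] @ b.windows[j])
            assert np.abs(s * oracle[j] - b.windows[j]).max() < 1e-6

    def test_derivative_windows_match_numerical_gradient(self):
        b = hermite_window_bank(3, 100.0, 2.0)
        for w, dw in zip(b.windows, b.derivative_windows):
            num = np.gradient(w)
            assert np.abs(num[5:-5] - dw[5:-5]).max() < 5e-4


class TestSTFT:
    fs = 100.0

    def test_zero_signal_gives_zero_matrix(self, small_cfg):
        b = hermite_window_bank(1, self.fs, small_cfg.half_width)
        rep = stft(np.zeros(2000), b.windows[0], small_cfg, self.fs)
        assert np.all(rep.matrix == 0)

    def test_impulse_sifting(self, small_cfg):
        b = hermite_window_bank(1, self.fs, small_cfg.half_width)
        w = b.windows[0]
        n = 2001
        x = np.zeros(n)
        center = 1000
        x[center] = 1.0
        rep = stft(x, w, small_cfg, self.fs)
        half = (len(w) - 1) // 2
        for col, t in enumerate(rep.time_grid):
            ti = int(round(t * self.fs))
            off = center - ti
            expect = abs(w[half + off]) if abs(off) <= half else 0.0
            assert np.allclose(np.abs(rep.matrix[col]), expect, atol=1e-12)

    def test_cosine_argmax_matches_direct_dft_oracle(self, small_cfg):
        x = tone(10.0, 40.0, self.fs)
        b = hermite_window_bank(1, self.fs, small_cfg.half_width)
        w = b.windows[0]
        rep = stft(x, w, small_cfg, self.fs)
        half = (len(w) - 1) // 2
        freqs = rep.freq_grid
        rng = np.random.default_rng(0)
        interior = np.flatnonzero(rep.interior())
        target_bin = np.argmin(np.abs(freqs - 10.0))
        for col in rng.choice(interior, 5, replace=False):
            ti = int(round(rep.time_grid[col] * self.fs))
            seg = x[ti - half:ti + half + 1] * w
            offs = np.arange(-half, half + 1)
            oracle = np.array([np.sum(seg * np.exp(-2j * np.pi * f * offs / self.fs))
                               for f in freqs])
            assert np.allclose(rep.matrix[col], oracle, atol=1e-9)
            assert np.argmax(np.abs(rep.matrix[col])) == target_bin

    def test_empty_signal_rejected(self, small_cfg):
        b = hermite_window_bank(1, self.fs, small_cfg.half_width)
        with pytest.raises(ValueError):
            stft(np.array([]), b.windows[0], small_cfg, self.fs)


class TestSynchrosqueeze:
    fs = 100.0

    def test_tone_concentrates_within_one_bin(self, small_cfg):
        rep = sst(tone(10.0), small_cfg, self.fs)
        P = rep.matrix[rep.interior()]
        fbin = np.argmin(np.abs(rep.freq_grid - 10.0))
        frac = P[:, fbin - 1:fbin + 2].sum(axis=1) / P.sum(axis=1)
        assert np.all(frac >= 0.95)

    def test_spectrogram_spreads_while_sst_does_not(self, small_cfg):
        from hrvtf.baselines import spectrogram
        x = tone(10.0)
        b = hermite_window_bank(1, self.fs, small_cfg.half_width)
        sp = spectrogram(x, b.windows[0], small_cfg, self.fs)
        col = sp.matrix[sp.interior()][0]
        assert (col >= col.max() / 2).sum() >= 3

    def test_zero_signal_gives_zero_output(self, small_cfg):
        rep = sst(np.zeros(2000), small_cfg, self.fs)
        assert np.all(rep.matrix == 0)

    def test_chirp_tracking_within_one_bin(self):
        fs = self.fs
        t = np.arange(0, 60, 1 / fs)
        f_inst = 5 + 10 * t / 60.0
        x = np.cos(2 * np.pi * np.cumsum(f_inst) / fs)
        cfg = ConceFTConfig(J=1, N=1, half_width=2.0, freq_lo=0, freq_hi=20,
                            n_freq_bins=401, hop=10)
        rep = sst(x, cfg, fs)
        am = rep.freq_grid[np.argmax(rep.matrix, axis=1)]
        truth = f_inst[(rep.time_grid * fs).astype(int)]
        df = rep.freq_grid[1] - rep.freq_grid[0]
        frac = np.mean(np.abs(am - truth)[rep.interior()] <= df)
        assert frac >= 0.95

    def test_shape_mismatch_rejected(self, small_cfg):
        b = hermite_window_bank(1, self.fs, small_cfg.half_width)
        v = stft(tone(10.0), b.windows[0], small_cfg, self.fs)
        import dataclasses
        bad = dataclasses.replace(v, matrix=v.matrix[:, :-1])
        with pytest.raises(ValueError):
            synchrosqueeze(v, bad)


class TestConceFT:
    fs = 100.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_degenerate_equals_single_window_sst(self, seed):
        x = tone(10.0, 30.0)
        cfg = ConceFTConfig(J=1, N=1, half_width=1.0, freq_lo=0, freq_hi=20,
                            n_freq_bins=128, hop=20, seed=seed)
        a = conceft(x, cfg, self.fs)
        b = sst(x, cfg, self.fs)
        assert np.array_equal(a.matrix, b.matrix)

    def test_nonnegative(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=3000)
        cfg = ConceFTConfig(J=2, N=5, half_width=1.0, freq_lo=0, freq_hi=20,
                            n_freq_bins=128, hop=20, seed=0)
        rep = conceft(x, cfg, self.fs)
        assert np.all(rep.matrix >= 0)
        assert np.all(np.isfinite(rep.matrix))

    def test_amplitude_scaling_covariance(self):
        x = tone(10.0, 30.0)
        cfg = ConceFTConfig(J=2, N=5, half_width=1.0, freq_lo=0, freq_hi=20,
                            n_freq_bins=128, hop=20, seed=0)
        r1 = conceft(x, cfg, self.fs)
        r2 = conceft(3.0 * x, cfg, self.fs)
        assert np.allclose(r2.matrix, 9.0 * r1.matrix,
                           rtol=1e-9, atol=1e-9 * r1.matrix.max())

    def test_time_shift_covariance_by_one_hop(self):
        x = tone(10.0, 30.0)
        cfg = ConceFTConfig(J=2, N=5, half_width=1.0, freq_lo=0, freq_hi=20,
                            n_freq_bins=128, hop=20, seed=0)
        xs = np.concatenate([np.zeros(cfg.hop), x[:-cfg.hop]])
        ra = conceft(x, cfg, self.fs)
        rb = conceft(xs, cfg, self.fs)
        both = ra.interior()[:-1] & ra.interior()[1:]
        A = ra.matrix[:-1][both]
        B = rb.matrix[1:][both]
        assert np.allclose(A, B, rtol=1e-9, atol=1e-9 * A.max())

    def test_seed_determinism(self):
        x = tone(10.0, 30.0)
        cfg = ConceFTConfig(J=2, N=10, half_width=1.0, freq_lo=0, freq_hi=20,
                            n_freq_bins=128, hop=20, seed=5)
        assert np.array_equal(conceft(x, cfg, self.fs).matrix,
                              conceft(x, cfg, self.fs).matrix)

    def test_averaging_stabilizes_ridge_cells(self):
        """For a fixed clean signal across noise realizations, the tvPS
        variance on strong (ridge) cells is smaller with many random window
        combinations than with one — the stability-to-noise property."""
        from hrvtf import arma_t4_noise, assemble_sim_signal

        base = default_sim_signal(seed=0, duration_s=120.0)
        comps = list(base.truth)
        cfg_many = ConceFTConfig(J=2, N=50, half_width=1.885, freq_lo=0,
                                 freq_hi=20, n_freq_bins=256, hop=50, seed=0)
        cfg_one = ConceFTConfig(J=2, N=1, half_width=1.885, freq_lo=0,
                                freq_hi=20, n_freq_bins=256, hop=50, seed=0)
        many, one = [], []
        for r in range(6):
            noise = arma_t4_noise(len(base.clean), seed=500 + r)
            sim = assemble_sim_signal(comps, noise, -2.0, fs=self.fs)
            many.append(conceft(sim.observed, cfg_many, self.fs).matrix)
            one.append(conceft(sim.observed, cfg_one, self.fs).matrix)
        vm = np.var(np.stack(many), axis=0)
        vo = np.var(np.stack(one), axis=0)
        mean_many = np.mean(np.stack(many), axis=0)
        cells = mean_many > 0.1 * mean_many.max()
        assert np.mean(vm[cells] < vo[cells]) >= 0.8


class TestMTSST:
    fs = 100.0

    def test_j1_equals_single_window_sst(self):
        x = tone(10.0, 30.0)
        cfg = ConceFTConfig(half_width=1.0, freq_lo=0, freq_hi=20,
                            n_freq_bins=128, hop=20)
        assert np.array_equal(mt_sst(x, 1, cfg, self.fs).matrix,
                              sst(x, cfg, self.fs).matrix)

    def test_multitaper_resolves_both_components(self):
        sim = default_sim_signal(seed=0, duration_s=300.0, target_snr_db=20.0)
        cfg = ConceFTConfig(half_width=1.885, freq_lo=0, freq_hi=20,
                            n_freq_bins=512, hop=50)
        rep = mt_sst(sim.observed, 6, cfg, self.fs)
        t = rep.time_grid
        df = rep.freq_grid[1] - rep.freq_grid[0]
        n = len(sim.observed)
        hits = []
        for comp in sim.truth:
            t0, t1 = comp.support
            on = (t >= t0 + 5) & (t <= t1 - 5) & rep.interior()
            truth = comp.inst_freq[np.clip((t * self.fs).astype(int), 0, n - 1)]
            # strongest bin within 1 Hz of the component's IF
            for col in np.flatnonzero(on):
                band = np.abs(rep.freq_grid - truth[col]) <= 1.0
                hits.append(rep.matrix[col][band].max()
                            >= 0.1 * rep.matrix[col].max())
        assert np.mean(hits) >= 0.8
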