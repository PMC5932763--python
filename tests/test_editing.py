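"""Beat features, SVM classification, segment exclusion, predictive interpolation."""

import numpy as np
import pandas as pd
import pytest

from hrvtf import (detect_r_peaks, exclude_low_quality_segments,
                   extract_beat_features, hourly_quantile,
                   predictive_interpolate, standardize_ecg, synth_ecg,
                   train_beat_classifier)
from hrvtf.editing import FEATURE_COLUMNS
from hrvtf.preprocess import RRSeries


def _rr(rr_ms):
    rr_ms = np.asarray(rr_ms, dtype=float)
    bt = np.concatenate([[0.0], np.cumsum(rr_ms)]) / 1000.0
    return RRSeries(beat_times=bt, rr=rr_ms.copy(),
                    status=np.array(["normal"] * len(rr_ms), dtype=object))


class TestFeatures:
    def test_periodic_record_features(self, clean_toy):
        pk = detect_r_peaks(clean_toy.record)
        f = extract_beat_features(clean_toy.record, pk)
        interior = f.iloc[10:-1]
        assert np.allclose(interior.dt_prev, interior.dt_next, atol=2.1)
        assert np.allclose(interior.dt_prev, interior.mean_rr10, atol=2.1)
        # edge beats carry explicit missing markers
        assert np.isnan(f.dt_prev.iloc[0]) and np.isnan(f.dt_next.iloc[-1])
        assert f.mean_rr10.iloc[:10].isna().all()

    def test_premature_beat_ratio(self, ectopic_toy):
        pk = detect_r_peaks(ectopic_toy.record)
        assert len(pk.indices) == len(ectopic_toy.true_r_peaks)
        f = extract_beat_features(ectopic_toy.record, pk)
        ect = np.flatnonzero(ectopic_toy.true_labels)
        ect = ect[ect >= 10]
        ratio = (f.dt_prev / f.mean_rr10).to_numpy()[ect]
        assert np.all(np.abs(ratio - 0.6) < 0.05)

    def test_amplitude_feature_tracks_beat_height(self, ectopic_toy):
        pk = detect_r_peaks(ectopic_toy.record)
        f = extract_beat_features(ectopic_toy.record, pk)
        amp = f.r_amp.to_numpy()
        ect = ectopic_toy.true_labels
        assert abs(amp[ect].mean() / amp[~ect].mean() - 1.6) < 0.1

    def test_too_few_beats_rejected(self, clean_toy):
        from hrvtf.preprocess import PeakList
        pk = PeakList(indices=clean_toy.true_r_peaks[:5],
                      slopes=np.ones(5), fs=clean_toy.record.fs)
        with pytest.raises(ValueError):
            extract_beat_features(clean_toy.record, pk)


class TestClassifier:
    def test_separable_data_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 6)), columns=FEATURE_COLUMNS)
        y = np.where(X.r_amp > 0, "abnormal", "sinus").astype(object)
        X.loc[:, "r_amp"] += np.where(y == "abnormal", 2.0, -2.0)
        m = train_beat_classifier(X, y)
        assert np.all(m.predict(X).labels == y)

    def test_toy_ecg_heldout_balanced_accuracy(self, ectopic_toy):
        pk = detect_r_peaks(ectopic_toy.record)
        f = extract_beat_features(ectopic_toy.record, pk)
        y = np.where(ectopic_toy.true_labels, "abnormal", "sinus").astype(object)
        half = len(y) // 2
        m = train_beat_classifier(f.iloc[:half], y[:half])
        pred = m.predict(f.iloc[half:]).labels
        yt = y[half:]
        sens = np.mean(pred[yt == "abnormal"] == "abnormal")
        spec = np.mean(pred[yt == "sinus"] == "sinus")
        assert (sens + spec) / 2 >= 0.95

    def test_no_signal_control_near_chance(self):
        rng = np.random.default_rng(42)
        n = 400
        X = pd.DataFrame(rng.normal(size=(n, 6)), columns=FEATURE_COLUMNS)
        y = np.where(rng.random(n) < 0.5, "abnormal", "sinus").astype(object)
        m = train_beat_classifier(X.iloc[:200], y[:200])
        pred = m.predict(X.iloc[200:]).labels
        yt = y[200:]
        sens = np.mean(pred[yt == "abnormal"] == "abnormal")
        spec = np.mean(pred[yt == "sinus"] == "sinus")
        assert abs((sens + spec) / 2 - 0.5) <= 0.10

    def test_single_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 6)),
                         columns=FEATURE_COLUMNS)
        y = np.array(["sinus"] * 50, dtype=object)
        with pytest.raises(ValueError):
            train_beat_classifier(X, y)


class TestSegmentExclusion:
    def _times(self, n):
        return np.linspace(0, 599.9, n)

    def test_79_percent_normal_excluded(self):
        lab = np.array(["sinus"] * 79 + ["abnormal"] * 21, dtype=object)
        assert exclude_low_quality_segments(lab, self._times(100)).all()

    def test_80_percent_normal_kept(self):
        lab = np.array(["sinus"] * 80 + ["abnormal"] * 20, dtype=object)
        assert not exclude_low_quality_segments(lab, self._times(100)).any()

    def test_all_normal_no_exclusions(self):
        lab = np.array(["sinus"] * 500, dtype=object)
        t = np.linspace(0, 3 * 600, 500)
        assert not exclude_low_quality_segments(lab, t).any()

    def test_only_bad_window_excluded(self):
        lab = np.array(["sinus"] * 100 + ["abnormal"] * 30 + ["sinus"] * 70, dtype=object)
        t = np.concatenate([np.linspace(0, 599, 100), np.linspace(600, 1199, 100)])
        exc = exclude_low_quality_segments(lab, t)
        assert not exc[:100].any() and exc[100:].all()


class TestPredictiveInterpolation:
    def test_constant_series_exact_replacement(self):
        rr = _rr([800.0] * 30)
        rr.rr[15] = 480.0
        ab = np.zeros(30, dtype=bool)
        ab[15] = True
        out = predictive_interpolate(rr, ab)
        assert out.rr[15] == 800.0
        assert out.status[15] == "interpolated"

    def test_periodic_pattern_dictates_replacement(self):
        pat = [800.0, 820.0] * 20
        rr = _rr(pat)
        ab = np.zeros(40, dtype=bool)
        ab[21] = True
        expected = pat[21]
        rr.rr[21] = 500.0
        out = predictive_interpolate(rr, ab)
        assert out.rr[21] == expected

    def test_adjacent_ectopic_and_pause_both_replaced(self):
        rr = _rr([800.0] * 40)
        rr.rr[20], rr.rr[21] = 480.0, 1120.0
        ab = np.zeros(40, dtype=bool)
        ab[20] = ab[21] = True
        out = predictive_interpolate(rr, ab)
        assert out.rr[20] == 800.0 and out.rr[21] == 800.0
        assert list(out.status[20:22]) == ["interpolated", "interpolated"]

    def test_normal_intervals_never_change(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(800, 30, 100)
        rr = _rr(vals)
        ab = np.zeros(100, dtype=bool)
        ab[[30, 60]] = True
        out = predictive_interpolate(rr, ab)
        assert np.array_equal(out.rr[~ab], vals[~ab])
        # replacements are values present among the normal intervals
        assert out.rr[30] in vals[~ab] and out.rr[60] in vals[~ab]

    def test_too_few_normals_rejected(self):
        rr = _rr([800.0] * 15)
        ab = np.zeros(15, dtype=bool)
        ab[0] = True
        with pytest.raises(ValueError):
            predictive_interpolate(rr, ab)

    def test_edited_hourly_medians_match_ectopic_free_truth(self):
        """Pipeline property: after editing a 10%-ectopic record, hourly RR
        medians agree with the ectopic-free ground truth within 2 ms."""
        from hrvtf.pipeline import _rhythm_abnormal_intervals
        from hrvtf.preprocess import correct_rr

        toy = synth_ecg(duration_s=3600.0, fs=200.0, mean_rr=800.0,
                        rr_jitter=25.0, ectopic_rate=0.10, seed=7)
        rec = standardize_ecg(toy.record)
        pk = detect_r_peaks(rec)
        rr = correct_rr(pk)
        abn = _rhythm_abnormal_intervals(rr)
        edited = predictive_interpolate(rr, abn)
        usable = edited.status != "excluded"
        hs = hourly_quantile(edited.beat_times[1:][usable], edited.rr[usable], 0.5)
        true_bt = toy.true_r_peaks / toy.record.fs
        norm = ~(toy.true_labels[1:] | toy.true_labels[:-1])
        hs_true = hourly_quantile(true_bt[1:][norm], toy.true_rr[norm], 0.5)
        m = min(len(hs.values), len(hs_true.values))
        assert np.abs(hs.values[:m] - hs_true.values[:m]).max() <= 2.0
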