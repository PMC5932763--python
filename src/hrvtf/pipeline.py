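"""End-to-end orchestration: raw ECG → edited RR/QTc → hourly series → tvPS → NRR.

Every stage's output is persisted so stages can be re-run independently, and
the full effective configuration is embedded in a JSON provenance file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as hio
from .editing import (BeatLabels, exclude_low_quality_segments,
                      extract_beat_features, predictive_interpolate)
from .preprocess import ECGRecord, RRSeries, correct_rr, detect_r_peaks, standardize_ecg
from .qt import qt_pipeline
from .ridge import extract_dominant_ridge, nrr_function
from .series import HourlySeries, fill_gaps, hourly_quantile
from .tf import HOURLY_FS_CPD, ConceFTConfig, conceft, hourly_config

log = logging.getLogger("hrvtf")

_KNOWN_KEYS = None  # populated lazily from the dataclass


@dataclass
class PipelineConfig:
    """Flat bag of every stage's tunables."""

    mains_hz: float = 60.0
    gammas: tuple[float, ...] = (0.01, 0.5, 0.99)
    min_coverage: float = 0.5
    qtc_window: int = 41
    band_halfwidth_cpd: float = 0.25
    smoothness_penalty: float = 0.1
    tf_J: int = 3
    tf_N: int = 100
    tf_half_width_hours: float = 48.0
    tf_freq_hi_cpd: float = 8.0
    tf_n_freq_bins: int = 256
    seed: int = 0
    use_classifier: bool = False  # rhythm-based abnormal flagging by default

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "gammas" in data:
            data["gammas"] = tuple(data["gammas"])
        return cls(**data)

    def tf_config(self) -> ConceFTConfig:
        return hourly_config(J=self.tf_J, N=self.tf_N,
                             half_width_hours=self.tf_half_width_hours,
                             freq_hi_cpd=self.tf_freq_hi_cpd,
                             n_freq_bins=self.tf_n_freq_bins, seed=self.seed)


@dataclass
class PipelineResult:
    rr: RRSeries
    qt_table: object
    hourly: dict[str, HourlySeries]
    tvps: dict[str, object]
    nrr: dict[str, object]
    counts: dict[str, int] = field(default_factory=dict)


def _rhythm_abnormal_intervals(rr: RRSeries, frac: float = 0.2) -> np.ndarray:
    """Simple rhythm rule: an interval deviating > frac from the local 11-beat
    median is abnormal (used when no trained classifier is supplied)."""
    v = rr.rr
    med = np.array([np.median(v[max(0, i - 5):min(len(v), i + 6)]) for i in range(len(v))])
    return np.abs(v - med) > frac * med


def run_pipeline(ecg_path: str | Path, config: PipelineConfig,
                 out_dir: str | Path, classifier=None) -> PipelineResult:
    """Execute the full chain on one recording, persisting all intermediates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(dataclasses.asdict(config), indent=1))

    record = hio.read_ecg(ecg_path)
    record = standardize_ecg(record, mains_hz=config.mains_hz)
    peaks = detect_r_peaks(record)
    log.info("detected %d R peaks", len(peaks.indices))
    rr = correct_rr(peaks)
    counts = {"beats_detected": int(len(peaks.indices)),
              "intervals": int(len(rr.rr)),
              "merged": int(np.sum(rr.status == "removed-spurious-merge")),
              "split": int(np.sum(rr.status == "split-inserted"))}

    # beat labelling: trained classifier if provided, else the rhythm rule
    if classifier is not None and config.use_classifier:
        feats = extract_beat_features(record, peaks)
        labels = classifier.predict(feats)
        beat_abn = labels.labels == "abnormal"
        abn_int = np.zeros(len(rr.rr), dtype=bool)
        m = min(len(beat_abn) - 1, len(abn_int))
        abn_int[:m] = beat_abn[1:m + 1]
    else:
        abn_int = _rhythm_abnormal_intervals(rr)
    # exclusion of low-quality 10-min segments, applied before interpolation
    int_labels = np.where(abn_int, "abnormal", "sinus").astype(object)
    excluded = exclude_low_quality_segments(int_labels, rr.beat_times[:-1])
    edited = predictive_interpolate(rr, abn_int & ~excluded)
    edited.status[excluded] = "excluded"
    counts["interpolated"] = int(np.sum(edited.status == "interpolated"))
    counts["excluded"] = int(np.sum(edited.status == "excluded"))
    hio.write_annotations(edited, out / "beats.csv", fs=record.fs)

    qts = qt_pipeline(record, peaks)
    qts.table.to_csv(out / "qt.csv", index=False, float_format=hio.FLOAT_FMT)

    interval_times = edited.beat_times[1:]
    usable = edited.status != "excluded"
    hourly: dict[str, HourlySeries] = {}
    for g in config.gammas:
        hs = hourly_quantile(interval_times[usable], edited.rr[usable], g,
                             source="RR", min_coverage=config.min_coverage)
        hourly[f"R_{g}"] = hs
        hio.write_series(hs, out / f"series_R_{g}.csv")
    qtab = qts.table
    qok = qtab["valid"].to_numpy(dtype=bool)
    if qok.sum() >= 2:
        qt_times = peaks.indices / record.fs
        for g in config.gammas:
            hs = hourly_quantile(qt_times[qok], qtab["qtc_ms"].to_numpy()[qok], g,
                                 source="QTc", min_coverage=config.min_coverage)
            hourly[f"Q_{g}"] = hs
            hio.write_series(hs, out / f"series_Q_{g}.csv")

    cfg_tf = config.tf_config()
    tvps, nrrs = {}, {}
    for name, hs in hourly.items():
        filled = fill_gaps(hs)
        win_len = 2 * int(round(cfg_tf.half_width * HOURLY_FS_CPD)) + 1
        if len(filled.values) < max(win_len, 8):
            log.info("series %s too short for the transform; skipped", name)
            continue
        rep = conceft(filled.values - np.mean(filled.values), cfg_tf, fs=HOURLY_FS_CPD)
        hio.write_tfrep(rep, out / f"tvps_{name}.csv")
        ridge = extract_dominant_ridge(rep, config.smoothness_penalty)
        res = nrr_function(rep, ridge, config.band_halfwidth_cpd)
        nrrs[name] = res
        tvps[name] = rep
        np.savetxt(out / f"nrr_{name}.csv",
                   np.column_stack([rep.time_grid, ridge.freq_value, res.nrr]),
                   delimiter=",", header="time_days,ridge_freq_cpd,nrr", comments="")
    (out / "counts.json").write_text(json.dumps(counts, indent=1))
    return PipelineResult(rr=edited, qt_table=qts.table, hourly=hourly,
                          tvps=tvps, nrr=nrrs, counts=counts)
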