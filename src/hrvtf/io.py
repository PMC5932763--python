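"""Plain-text file formats: ECG CSV, beat annotations, hourly series, tvPS.

Everything round-trips: a tvPS is a dense CSV matrix plus a JSON sidecar
carrying the grids, method tag and configuration; numbers are written with 12
significant digits.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ECGRecord, RRSeries
from .series import HourlySeries
from .tf import ConceFTConfig, TFRep

FLOAT_FMT = "%.12g"


class FormatError(ValueError):
    """Malformed input file."""


def read_ecg(path: str | Path, fs: float | None = None) -> ECGRecord:
    """Read a two-column CSV (header: time_s, mv) into an ECGRecord.

    The sampling rate is inferred from the time column unless given.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    cols = [c.strip().lower() for c in df.columns]
    if "time_s" not in cols or "mv" not in cols:
        raise FormatError(f"{path}: expected header columns 'time_s,mv', got {list(df.columns)}")
    df.columns = cols
    t = df["time_s"].to_numpy(dtype=float)
    v = df["mv"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.flatnonzero(dt <= 0)[0]) + 2  # header is line 1
        raise FormatError(f"{path}: non-increasing time at line {bad}")
    fs_inferred = 1.0 / np.median(dt)
    return ECGRecord(samples=v, fs=fs or float(fs_inferred), start_time=float(t[0]))


def write_ecg(record: ECGRecord, path: str | Path) -> None:
    t = record.start_time + np.arange(len(record.samples)) / record.fs
    pd.DataFrame({"time_s": t, "mv": record.samples}).to_csv(
        Path(path), index=False, float_format=FLOAT_FMT)


def write_annotations(rr: RRSeries, path: str | Path, fs: float = 500.0) -> None:
    """Beat annotations: sample_index, time_s, flag (flag of the following interval)."""
    flags = np.concatenate([rr.status, ["end"]])
    pd.DataFrame({
        "sample_index": np.round(rr.beat_times * fs).astype(int),
        "time_s": rr.beat_times,
        "flag": flags,
    }).to_csv(Path(path), index=False, float_format=FLOAT_FMT)


def write_series(series: HourlySeries, path: str | Path) -> None:
    interp = series.interpolated if series.interpolated is not None \
        else np.zeros(len(series.values), dtype=bool)
    pd.DataFrame({
        "hour_index": series.hours(),
        "value": series.values,
        "coverage": series.coverage,
        "interpolated_flag": interp.astype(int),
        "gamma": series.gamma,
        "source": series.source,
    }).to_csv(Path(path), index=False, float_format=FLOAT_FMT)


def read_series(path: str | Path) -> HourlySeries:
    df = pd.read_csv(Path(path))
    interp = df["interpolated_flag"].to_numpy(dtype=bool) if "interpolated_flag" in df \
        else None
    return HourlySeries(values=df["value"].to_numpy(dtype=float),
                        gamma=float(df["gamma"].iloc[0]),
                        source=str(df["source"].iloc[0]),
                        coverage=df["coverage"].to_numpy(dtype=float),
                        interpolated=interp)


def write_tfrep(rep: TFRep, path: str | Path) -> None:
    """Dense matrix CSV plus a JSON sidecar (grids, method, config, boundary)."""
    path = Path(path)
    mat = rep.matrix
    if np.iscomplexobj(mat):
        raise ValueError("complex STFT matrices are not serialized; store power instead")
    # full float64 precision so the matrix round-trips exactly
    np.savetxt(path, mat, delimiter=",", fmt="%.17g")
    sidecar = {
        "method": rep.method,
        "time_grid": [float(v) for v in rep.time_grid],
        "freq_grid": [float(v) for v in rep.freq_grid],
        "boundary": [bool(b) for b in rep.boundary] if rep.boundary is not None else None,
        "fs": rep.fs,
        "config": dataclasses.asdict(rep.config) if rep.config is not None else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_tfrep(path: str | Path) -> TFRep:
    path = Path(path)
    mat = np.loadtxt(path, delimiter=",")
    side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cfg = ConceFTConfig(**side["config"]) if side.get("config") else None
    boundary = np.asarray(side["boundary"], dtype=bool) if side.get("boundary") is not None else None
    return TFRep(time_grid=np.asarray(side["time_grid"]),
                 freq_grid=np.asarray(side["freq_grid"]),
                 matrix=np.atleast_2d(mat), method=side["method"], config=cfg,
                 boundary=boundary, fs=side.get("fs"))


def write_sim_signal(sim, path: str | Path) -> None:
    """Simulated signal as time/value CSV plus a JSON truth sidecar."""
    path = Path(path)
    t = np.arange(len(sim.observed)) / sim.fs
    pd.DataFrame({"time_s": t, "value": sim.observed}).to_csv(
        path, index=False, float_format=FLOAT_FMT)
    truth = {
        "fs": sim.fs,
        "snr_db": sim.snr_db,
        "components": [
            {"support": list(c.support),
             "amplitude": [float(v) for v in c.amplitude],
             "inst_freq": [float(v) for v in c.inst_freq]}
            for c in sim.truth
        ],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(truth))
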