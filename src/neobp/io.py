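"""Record and database I/O.

Waveform channels round-trip through columnar CSV (time_s, value) with
a JSON metadata sidecar, or through a single HDF5 container per
patient. The paired training database persists as one HDF5 file
(windows matrix + per-window metadata table); schema version is written
alongside.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .beats import BPTriplet
from .quality import QualityScore
from .simulate import GroundTruth, PatientDataset, WaveformRecord
from .sync import ExclusionLogEntry, PairedWindow

__all__ = ["write_record_csv", "read_record_csv", "write_patient_dir",
           "write_patient_h5", "read_patient_h5", "write_paired_db",
           "read_paired_db", "write_exclusion_log"]

DB_SCHEMA_VERSION = 1


class FormatError(ValueError):
    pass


def write_record_csv(record: WaveformRecord, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": record.time(), "value": record.samples})
    df.to_csv(path, index=False, float_format="%.10g")
    sidecar = {"patient_id": record.patient_id, "source": record.source,
               "fs_hz": record.fs_hz, "t0": record.t0,
               "n_samples": len(record.samples)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_record_csv(path: str | Path) -> WaveformRecord:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "value"]:
        raise FormatError(f"{path}: expected columns time_s,value, got {list(df.columns)}")
    t = df["time_s"].to_numpy()
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 1
        raise FormatError(f"{path}: non-monotone time column at row {bad}")
    meta_path = path.with_suffix(".json")
    if not meta_path.exists():
        raise FormatError(f"{path}: missing metadata sidecar {meta_path.name}")
    meta = json.loads(meta_path.read_text())
    rec = WaveformRecord(meta["patient_id"], meta["source"], meta["fs_hz"],
                         df["value"].to_numpy(), t0=meta.get("t0", 0.0))
    if len(t) > 1:
        fs_obs = 1.0 / float(np.median(np.diff(t)))
        if abs(fs_obs - rec.fs_hz) / rec.fs_hz > 0.01:
            raise FormatError(f"{path}: sampling rate {fs_obs:.3f} Hz disagrees "
                              f"with sidecar fs_hz={rec.fs_hz}")
    return rec


def _truth_frame(truth: GroundTruth) -> pd.DataFrame:
    return pd.DataFrame({"beat_start": truth.beat_starts,
                         "beat_end": truth.beat_ends,
                         "sbp_mmhg": truth.sbp_mmhg,
                         "dbp_mmhg": truth.dbp_mmhg,
                         "map_mmhg": truth.map_mmhg})


def write_patient_dir(ds: PatientDataset, outdir: str | Path) -> Path:
    """One directory per patient: channel CSVs, ground-truth CSV, and a
    JSON sidecar with demographics and the simulation seed."""
    outdir = Path(outdir) / ds.meta.patient_id
    outdir.mkdir(parents=True, exist_ok=True)
    write_record_csv(ds.ial, outdir / "ial.csv")
    for i, s in enumerate(ds.sensors):
        write_record_csv(s, outdir / f"sensor_ch{i}.csv")
    _truth_frame(ds.truth).to_csv(outdir / "ground_truth.csv", index=False)
    meta = {"meta": asdict(ds.meta), "true_lag_samples": int(ds.truth.true_lag_samples),
            "seed": ds.config.seed, "fs_hz": ds.config.fs_hz}
    (outdir / "patient.json").write_text(json.dumps(meta, indent=1))
    return outdir


def write_patient_h5(ds: PatientDataset, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["patient_id"] = ds.meta.patient_id
        f.attrs["fs_hz"] = ds.config.fs_hz
        f.attrs["meta_json"] = json.dumps(asdict(ds.meta))
        f.attrs["true_lag_samples"] = int(ds.truth.true_lag_samples)
        f.create_dataset("ial", data=ds.ial.samples)
        for i, s in enumerate(ds.sensors):
            f.create_dataset(f"sensor_ch{i}", data=s.samples)
        g = f.create_group("truth")
        for name in ("beat_starts", "beat_ends", "sbp_mmhg", "dbp_mmhg", "map_mmhg"):
            g.create_dataset(name, data=getattr(ds.truth, name))


def read_patient_h5(path: str | Path) -> tuple[WaveformRecord, list[WaveformRecord], GroundTruth]:
    with h5py.File(path, "r") as f:
        pid = f.attrs["patient_id"]
        fs = float(f.attrs["fs_hz"])
        ial = WaveformRecord(pid, "IAL", fs, f["ial"][:])
        sensors = [WaveformRecord(pid, f"sensor_ch{i}", fs, f[f"sensor_ch{i}"][:])
                   for i in range(4)]
        g = f["truth"]
        truth = GroundTruth(g["beat_starts"][:], g["beat_ends"][:],
                            g["sbp_mmhg"][:], g["dbp_mmhg"][:], g["map_mmhg"][:],
                            int(f.attrs["true_lag_samples"]))
    return ial, sensors, truth


def write_paired_db(windows: Sequence[PairedWindow], path: str | Path) -> None:
    if not windows:
        raise ValueError("refusing to write an empty paired database")
    mat = np.stack([w.sensor_samples for w in windows])
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = DB_SCHEMA_VERSION
        f.create_dataset("windows", data=mat)
        meta = pd.DataFrame({
            "window_id": [w.window_id for w in windows],
            "patient_id": [w.patient_id for w in windows],
            "sbp": [w.bp_truth.sbp for w in windows],
            "dbp": [w.bp_truth.dbp for w in windows],
            "map": [w.bp_truth.map for w in windows],
            "age_days": [w.age_days for w in windows],
            "weight_kg": [w.weight_kg for w in windows],
            "q": [w.quality.q for w in windows],
            "r": [w.quality.r if w.quality.r is not None else np.nan for w in windows],
            "channel": [w.channel for w in windows],
            "local_lag": [w.local_lag for w in windows],
        })
        g = f.create_group("meta")
        for col in meta.columns:
            data = meta[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            g.create_dataset(col, data=data)


def read_paired_db(path: str | Path) -> list[PairedWindow]:
    out = []
    with h5py.File(path, "r") as f:
        if int(f.attrs.get("schema_version", -1)) != DB_SCHEMA_VERSION:
            raise FormatError(f"{path}: unsupported paired-db schema")
        mat = f["windows"][:]
        g = f["meta"]
        n = mat.shape[0]
        for i in range(n):
            r = float(g["r"][i])
            out.append(PairedWindow(
                window_id=g["window_id"][i].decode(),
                patient_id=g["patient_id"][i].decode(),
                sensor_samples=mat[i],
                bp_truth=BPTriplet(float(g["sbp"][i]), float(g["dbp"][i]),
                                   float(g["map"][i])),
                age_days=float(g["age_days"][i]),
                weight_kg=float(g["weight_kg"][i]),
                quality=QualityScore(q=float(g["q"][i]),
                                     r=None if np.isnan(r) else r),
                channel=int(g["channel"][i]),
                local_lag=int(g["local_lag"][i])))
    return out


def write_exclusion_log(log: Sequence[ExclusionLogEntry], path: str | Path) -> None:
    pd.DataFrame([asdict(e) for e in log]).to_csv(path, index=False)
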