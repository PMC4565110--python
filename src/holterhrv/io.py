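"""CSV readers and writers for ECG records, annotations and EP pulse waveforms.

One CSV dialect per object, documented in the README:

* ECG: comment header lines ``# key=value`` (fs_hz, start_clock, patient_id,
  session), then ``time_s`` plus one column per lead (µV, 3 decimals).
* Ground truth / annotations: one row per beat.
* EP waveforms: long format, one row per sample, grouped by
  (patient_id, tumor_id, train_id).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BeatSeries,
    EcgRecord,
    FormatError,
    GroundTruth,
    PulseTrainRecord,
    format_clock,
    parse_clock,
)

ECG_PRECISION = 3  # decimals of µV retained by the CSV round trip


def write_ecg(rec: EcgRecord, path: str | Path) -> None:
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.fs_hz
    df = pd.DataFrame({"time_s": t})
    for name in rec.lead_names:
        df[name] = rec.lead(name)
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={rec.fs_hz:g}\n")
        fh.write(f"# start_clock={format_clock(rec.start_clock_s)}\n")
        fh.write(f"# patient_id={rec.patient_id}\n")
        fh.write(f"# session={rec.session}\n")
        df.to_csv(fh, index=False, float_format=f"%.{ECG_PRECISION}f")


def read_ecg(path: str | Path, leads: list[str] | None = None) -> EcgRecord:
    """Read an ECG CSV; ``leads`` optionally restricts/validates the lead set."""
    path = Path(path)
    meta: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, skiprows=n_header)
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing 'time_s' column")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise FormatError(f"{path}: fewer than two samples")
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > 1e-6):
        raise FormatError(f"{path}: non-uniform sampling in 'time_s'")
    fs = float(meta.get("fs_hz", 1.0 / dt[0]))
    lead_names = [c for c in df.columns if c != "time_s"]
    if leads is not None:
        missing = [ld for ld in leads if ld not in lead_names]
        if missing:
            raise FormatError(f"{path}: missing lead column(s) {missing}")
        lead_names = list(leads)
    signals = df[lead_names].to_numpy().T
    return EcgRecord(
        signals=signals,
        fs_hz=fs,
        lead_names=lead_names,
        start_clock_s=parse_clock(meta.get("start_clock", 0.0)),
        patient_id=meta.get("patient_id", ""),
        session=meta.get("session", ""),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": truth.r_times_s,
            "label": truth.labels,
            "q_s": truth.q_times_s,
            "t_s": truth.t_times_s,
            "st_flag": truth.st_flags.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.6f")


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path)
    required = {"time_s", "label", "q_s", "t_s", "st_flag"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing column(s) {sorted(required - set(df.columns))}")
    return GroundTruth(
        r_times_s=df["time_s"].to_numpy(),
        q_times_s=df["q_s"].to_numpy(),
        t_times_s=df["t_s"].to_numpy(),
        labels=df["label"].to_numpy(dtype="<U1"),
        st_flags=df["st_flag"].to_numpy(dtype=bool),
    )


def write_annotations(bs: BeatSeries, path: str | Path) -> None:
    """Beat annotations: sample index, clock time, label, ST flag."""
    clock = bs.start_clock_s + bs.r_idx / bs.fs_hz
    pd.DataFrame(
        {
            "sample_idx": bs.r_idx,
            "clock_time": [format_clock(c) for c in clock],
            "label": bs.labels,
            "st_flag": bs.st_dev.astype(int),
        }
    ).to_csv(path, index=False)


def write_pulse_records(records: list[PulseTrainRecord], path: str | Path) -> None:
    frames = []
    for r in records:
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": r.patient_id,
                    "tumor_id": r.tumor_id,
                    "train_id": r.train_id,
                    "time_s": r.time_s,
                    "voltage_v": r.voltage_v,
                    "current_a": r.current_a,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9g")


def read_pulse_records(path: str | Path) -> list[PulseTrainRecord]:
    """Parse EP waveform CSV into trains grouped by (patient, tumor, train).

    Rows may arrive in any order; they are sorted by time within each train.
    Duplicate timestamps within a train are a format error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    required = {"patient_id", "tumor_id", "train_id", "time_s", "voltage_v", "current_a"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing column(s) {sorted(required - set(df.columns))}")
    records = []
    for (pid, tid, trid), grp in df.groupby(
        ["patient_id", "tumor_id", "train_id"], sort=True
    ):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise FormatError(
                f"{path}: non-monotone time within train {trid} "
                f"(patient {pid}, tumor {tid})"
            )
        records.append(
            PulseTrainRecord(
                time_s=t,
                voltage_v=grp["voltage_v"].to_numpy(),
                current_a=grp["current_a"].to_numpy(),
                train_id=int(trid),
                tumor_id=str(tid),
                patient_id=str(pid),
            )
        )
    return records
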