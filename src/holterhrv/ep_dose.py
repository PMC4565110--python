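"""Electroporation-pulse dosimetry from recorded voltage/current waveforms.

Per tumor: the representative voltage (and current) is the median over trains
of the per-train median of within-pulse means — robust to occasional aborted
or noisy pulses.  Energy is the time integral of instantaneous power
V(t)*I(t) over all detected pulses (trapezoidal rule).  Per patient: energies
sum over tumors; where several tumors were treated the largest per-tumor
average voltage and current are carried forward.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import AnalysisError, PatientDose, PulseTrainRecord, TumorDose

V_THRESHOLD_FRAC = 0.10
MERGE_GAP_S = 10e-6


def pulse_boundaries(
    rec: PulseTrainRecord, v_threshold_frac: float = V_THRESHOLD_FRAC
) -> list[tuple[int, int]]:
    """Maximal sample runs where |V| >= frac * max|V|; gaps < 10 µs merged.

    Returns half-open index pairs ``(start, end)``; an all-quiet waveform
    yields an empty list with a warning.
    """
    v = np.abs(rec.voltage_v)
    vmax = v.max() if v.size else 0.0
    if vmax <= 0:
        warnings.warn(f"train {rec.train_id}: no pulses found (zero waveform)")
        return []
    above = v >= v_threshold_frac * vmax
    if not np.any(above):
        warnings.warn(f"train {rec.train_id}: no pulses found")
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    # merge runs separated by less than 10 µs
    merged: list[tuple[int, int]] = []
    for s, e in zip(run_starts, run_ends):
        if merged and rec.time_s[s] - rec.time_s[merged[-1][1] - 1] < MERGE_GAP_S:
            merged[-1] = (merged[-1][0], int(e))
        else:
            merged.append((int(s), int(e)))
    return merged


def tumor_dose(trains: list[PulseTrainRecord], tumor_id: str | None = None) -> TumorDose:
    """Median-of-medians averages and integrated energy for one tumor."""
    if not trains:
        raise AnalysisError("tumor_dose: no trains")
    if tumor_id is None:
        tumor_id = trains[0].tumor_id
    train_med_v: list[float] = []
    train_med_i: list[float] = []
    energy = 0.0
    n_pulses = 0
    for tr in trains:
        bounds = pulse_boundaries(tr)
        if not bounds:
            warnings.warn(f"tumor {tumor_id}: train {tr.train_id} has no pulses, excluded")
            continue
        pulse_v = [float(np.mean(tr.voltage_v[s:e])) for s, e in bounds]
        pulse_i = [float(np.mean(tr.current_a[s:e])) for s, e in bounds]
        train_med_v.append(float(np.median(pulse_v)))
        train_med_i.append(float(np.median(pulse_i)))
        for s, e in bounds:
            energy += float(
                np.trapezoid(tr.voltage_v[s:e] * tr.current_a[s:e], tr.time_s[s:e])
            )
        n_pulses += len(bounds)
    if not train_med_v:
        raise AnalysisError(f"tumor_dose: no usable trains for tumor {tumor_id}")
    return TumorDose(
        tumor_id=tumor_id,
        n_pulses=n_pulses,
        avg_voltage_v=float(np.median(train_med_v)),
        avg_current_a=float(np.median(train_med_i)),
        energy_j=energy,
    )


def patient_dose(tumors: list[TumorDose], patient_id: str = "") -> PatientDose:
    """Patient totals: summed energy/pulses, maxima of per-tumor averages."""
    if not tumors:
        raise AnalysisError("patient_dose: no tumors")
    return PatientDose(
        patient_id=patient_id,
        tumors=list(tumors),
        total_energy_j=float(sum(t.energy_j for t in tumors)),
        max_avg_voltage_v=float(max(t.avg_voltage_v for t in tumors)),
        max_avg_current_a=float(max(t.avg_current_a for t in tumors)),
        total_pulses=int(sum(t.n_pulses for t in tumors)),
    )


def dose_from_records(records: list[PulseTrainRecord]) -> list[PatientDose]:
    """Group waveform records by patient and tumor and compute all doses."""
    by_patient: dict[str, dict[str, list[PulseTrainRecord]]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, {}).setdefault(r.tumor_id, []).append(r)
    doses = []
    for pid in sorted(by_patient):
        tumors = [
            tumor_dose(trs, tumor_id=tid) for tid, trs in sorted(by_patient[pid].items())
        ]
        doses.append(patient_dose(tumors, patient_id=pid))
    return doses
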