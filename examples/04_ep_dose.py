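"""Quantify electroporation pulse delivery for a two-tumor patient.

Each tumor receives trains of eight 100 µs rectangular pulses.  The
per-tumor average voltage/current is the median over trains of per-train
medians; energy integrates V(t)*I(t) over the detected pulses.  For the
first (ideal, 1000 V into 100 ohm) tumor the energy is exactly
8 pulses x V^2*tau/R = 8 J per train.
"""

import holterhrv as h

tumors = []
specs = [
    ("T1", h.EpSimConfig(n_trains=2, amplitude_v=1000.0, load_ohm=100.0,
                         waveform_fs_hz=1e6, seed=4)),
    ("T2", h.EpSimConfig(n_trains=3, amplitude_v=2100.0, load_ohm=80.0,
                         waveform_fs_hz=1e6, droop_frac=0.05, noise_frac=0.01,
                         seed=5)),
]
for tumor_id, cfg in specs:
    trains = h.generate_ep_waveforms(cfg, tumor_id=tumor_id, patient_id="P1")
    tumors.append(h.tumor_dose(trains, tumor_id=tumor_id))

dose = h.patient_dose(tumors, patient_id="P1")
for t in dose.tumors:
    print(f"{t.tumor_id}: {t.n_pulses} pulses, "
          f"{t.avg_voltage_v:7.1f} V, {t.avg_current_a:5.2f} A, "
          f"{t.energy_j:7.3f} J")
print(f"patient total: {dose.total_pulses} pulses, "
      f"max {dose.max_avg_voltage_v:.0f} V / {dose.max_avg_current_a:.2f} A, "
      f"{dose.total_energy_j:.3f} J")
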