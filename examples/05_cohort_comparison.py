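"""Full before/after cohort analysis on synthetic patients.

Builds a 6-patient cohort whose after-sessions have the mean RR interval
reduced by 150 ms (a faster post-operative heart rate), runs the complete
pipeline (detection, night-window selection, HRV, EP dose) on a reduced
two-segment night window, and prints the comparison tables.  The mean-NN row
comes out significant (all six paired differences negative gives the
smallest attainable exact two-sided p, 2/2^6 = 0.03125), and so do measures
mechanically coupled to heart rate (ppQTc via Bazett's sqrt(RR); RMSSD,
pNN50 and SD1 via the beat-to-beat sampling of the modulations).  The
spectral balance nLF/nHF, which has no injected effect, stays flat, and the
dose regressions show no association because dose and RR shift are
independent by construction.
"""

import holterhrv as h

cfg = h.make_synthetic_cohort(n_patients=6, seed=11, n_segments=2,
                              delta_rr_ms=150.0)
report = h.run(cfg)

print("== Before/after comparison (paired exact Wilcoxon) ==")
print(report.comparison_table.to_string(index=False,
                              float_format=lambda v: f"{v:10.3f}"))
print("\n== Regression of HRV changes on pulse-delivery parameters (p) ==")
cols = ["delta_parameter"] + [c for c in report.regression_table.columns if c.startswith("p_")]
print(report.regression_table[cols].to_string(index=False,
                                    float_format=lambda v: f"{v:8.3f}"))
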