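# Methods

`holterhrv` implements a post-operative cardiac-safety analysis for
treatments that deliver high-voltage electroporation (EP) pulses near the
heart: night-window Holter ECG analysis (beat detection and classification,
HRV, peak-to-peak QTc, ST screening), EP pulse dosimetry, and paired
before/after statistics.  This note records the models, conventions and
numerical choices, and what the synthetic validation does and does not show.

## Conventions

Signal samples are in µV; voltage/current in V and A; time in seconds;
indices 0-based; windows half-open `[start, end)`.  Clock time-of-day is
seconds since midnight, carried by the first sample of each record; all
analysis windows are defined in clock time.  Medians of even-length sets are
the mean of the two middle values, everywhere.

## Synthetic ECG model

Each heartbeat is a sum-of-Gaussians PQRST template (P, Q, R, S, T
components with fixed amplitudes, centers and widths relative to the R peak;
a per-lead scale table gives the 9 ambulatory leads their relative
amplitudes and polarities).  Beat times follow

```
RR(t) = mean_rr + a_lf sin(2π f_lf t) + a_hf sin(2π f_hf t) + ε,
```

with `f_lf` in the LF band (default 0.10 Hz), `f_hf` in the HF band
(default 0.25 Hz) and ε white jitter with RMS `rr_jitter_ms` (default 5 ms —
a realistic residual beat-to-beat variability; real NN spectra are broadband,
never pure tones).  A sinusoidal modulation of amplitude `a` contributes
`a²/2` to RR variance and the same power to its band, which is what the
spectral-recovery tests exploit.

Abnormal (premature-ventricular-like) beats occur with probability
`ectopic_rate` per beat: QRS widened ×2.5, inverted T, no P wave, preceding
RR shortened 20–40%, following RR lengthened so the two-beat span is
preserved (full compensatory pause).  ST-level shifts are a smooth plateau
over ≈[R+45, R+190] ms applied to a configurable fraction of beats.
Template peak positions are known analytically, so the emitted ground truth
(R/Q/T times, labels, ST flags) is an exact detector oracle.

Not emulated: realistic 12-lead morphology, P-wave pathology, baseline
wander, electrode-motion artifacts, non-white noise, arrhythmia taxonomy
beyond normal/abnormal, and circadian non-stationarity beyond the linear
trends the pipeline removes.  Passing tests therefore demonstrate
correctness of the *algorithms* under controlled conditions, not detector
performance on clinical recordings.

## Beat detection and classification

Detection is Pan-Tompkins style: 5–15 Hz band-pass (order-2 Butterworth,
zero-phase), squared derivative, 150 ms moving-window integration, candidate
peaks at ≥200 ms spacing, threshold at 20% of the upper-quartile candidate
height, refinement to the local extremum of the band-passed signal.  Q is
the raw-signal minimum in [R−80, R−10) ms; T the dominant extremum relative
to the record median in [R+120 ms, R+0.6·RR).

A beat is labelled abnormal when QRS width (at 25% of local band-passed
amplitude) exceeds 1.5× the running median of normal widths, when its RR
falls outside [0.8, 1.2]× the running median of the last 8 normal RR, or
when correlation with the running normal-beat template (mean of recent
normal snippets, R±100 ms) drops below 0.9.  Q/T locations are kept only
for normal beats.  The beat following a fully compensated ectopic ends a
lengthened RR and is deliberately allowed to fail the RR rule — erring
toward exclusion is the safe direction for downstream NN analysis.

ST screening is a documented simple operator (commercial Holter ST
algorithms are proprietary): ST level = mean over [R+60, R+80) ms minus PQ
baseline (mean over [R−120, R−80) ms); flagged when |level| ≥ 100 µV
(default).

Reporting conventions, pinned by a published 10-patient reference cohort:
abnormal percentage uses all beats (N+A) as denominator, ST percentage uses
normal beats only; percentages round to 3 decimals.

## Night window and subsegment selection

The analysis window defaults to 00:00–04:00 (minimal activity, most
stationary signal) and is divided into twelve 20-min segments.  Each segment
is scanned from its beginning on a 1-s grid for the earliest 5-min window
with strictly less than 1% abnormal beats that starts ≥10 min after the end
of the previously accepted window; the threshold escalates in 1% steps to
at most 5%.  A segment with no qualifying window at 5% is marked not
accepted and simply omitted downstream (the behaviour in that case is this
package's choice).  Spacing is measured accepted-to-accepted.  A window with
no beats counts as 0% abnormal; it cannot occur with physiologic input.
The scanner is verified equivalent to an exhaustive brute-force reference on
randomized annotation streams.

## HRV measures

Per accepted subsegment: intervals adjacent to an abnormal beat are replaced
by a cubic spline through the clean (time, NN) points (editing beyond a 5%
abnormal-beat burden is refused).  The irregular series is spline-fitted,
evaluated at 1 kHz and decimated to 4 Hz (no extra anti-alias filter — the
spline curve is already smooth relative to the 2 Hz Nyquist for physiologic
NN series; evaluation is clamped to the data support to avoid edge
extrapolation).  Linear detrending precedes all measures except mean NN and
the Poincaré descriptors.

Time domain: mean NN (raw values); SDNN, SDSD with sample variance
(1/(n−1)); RMSSD; pNN50 counts |ΔNN| > 50 ms (strict) against the total
number of NN intervals — the convention the reference tables use.
`time_domain_measures(..., detrend=False)` applies the textbook definitions
to the values as given; the pipeline default detrends first.

Poincaré: population-variance closed forms, SD1 = √(Var(ΔNN)/2),
SD2 = √(2·Var(NN) − Var(ΔNN)/2), under which SD1 = RMSSD/√2 exactly
(property-tested).

Frequency domain: Welch (Hamming window, 256 samples = 64 s, 50% overlap,
per-window mean removal) and an order-16 autoregressive model fitted with
the Burg method (coefficients from statsmodels).  Both PSDs are one-sided in
ms²/Hz; LF = 0.04–0.15 Hz, HF = 0.15–0.40 Hz by trapezoidal integration
with interpolated band edges; nLF = 100·LF/(LF+HF), nHF its exact
complement; LF/HF is NaN when HF = 0.  The AR spectrum is integrated
numerically on a 1024-point uniform grid augmented with points clustered
around each pole frequency at its bandwidth scale (an arctangent stretch),
because the near-Lorentzian peaks of a high-resolution AR model would
otherwise be under-resolved; with this refinement Welch and Burg band powers
agree within a few percent on two-tone test series, matching the observation
that the two estimators are practically indistinguishable on this task.

## ppQTc

ppQT is the Q-peak→T-peak interval of a normal beat (peak locations are far
more reliable than Q onset/T end); ppQTc = ppQT[ms]/√(RR[s]) (Bazett), with
RR the interval ending at the beat's R peak and both neighbours normal.
Per-patient summary is the median over all eligible beats of the selected
subsegments (not the raw 4-h series) — the subsegments are the unit the rest
of the analysis uses.

## EP dosimetry

Pulses are maximal runs where |V| ≥ 10% of the train's peak |V|, with gaps
< 10 µs merged.  Per train, the representative voltage/current is the median
over pulses of within-pulse means; per tumor, the median of train medians
(robust to aborted or noisy trains).  Energy integrates V(t)·I(t)
trapezoidally over detected pulses; for ideal rectangular pulses this equals
V²τ/R per pulse to machine precision.  Patient totals sum tumor energies and
pulse counts; where several tumors were treated, the largest per-tumor
average voltage and current are carried into the statistics.

## Statistics

Paired comparisons use the exact Wilcoxon signed-rank test: zero differences
dropped, average ranks for ties, and the two-sided p from the exact
distribution of the positive-rank sum built by dynamic programming over
doubled ranks (n ≤ 25; normal approximation with tie correction beyond).
Quartiles of changes use linear interpolation between order statistics.  No
multiple-testing correction is applied; rows with raw p < 0.05 are flagged
as-is.  Dose association is ordinary least squares with the two-sided t-test
on the slope.  Calibration (type-I rate ≈ 5%, power > 0.8 for a 150 ms mean
NN reduction at n = 10) is verified at the statistical layer on paired
per-patient values with a within-patient night-to-night SD of 50 ms; exact
tests at n = 10 have a largest attainable two-sided level of 0.0488, so the
empirical rate sits slightly below nominal.

## Problem sizes

The default night window (twelve 20-min segments) matches the clinical
setting.  The test suite and the acceptance script run the end-to-end
pipeline on reduced cohorts (2–8 patients, two 20-min segments per night
window) with full-length 5-min subsegments, so spectral resolution and all
per-segment computations are identical to the full-scale configuration;
only the number of segments and patients is reduced.  Statistical
calibration runs 500 repetitions at the per-patient-value layer, where the
tested machinery (the exact Wilcoxon row computation) is exercised directly.

## Known limitations

* The beat classifier's running template assumes the recording starts with
  predominantly normal beats.
* ST screening is amplitude-threshold only; no slope/shape analysis.
* The simulator's fixed Q→T template distance makes ppQTc mechanically
  dependent on RR, so cohort-level ppQTc changes track heart-rate changes.
* `edit_rr` requires ≥4 clean intervals and refuses >5% abnormal burden;
  heavily ectopic segments are excluded rather than repaired.
* WFDB and vendor Holter formats are not read; the CSV dialects documented
  in the README are the interchange formats.
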