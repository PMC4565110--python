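"""Heart-rate-variability measures for 5-min NN subsegments.

Processing chain per subsegment:

1. :func:`rr_from_beats` — RR intervals from classified beats; an interval is
   tainted when either endpoint beat is abnormal.
2. :func:`edit_rr` — tainted intervals replaced by a cubic spline fitted
   through the clean (time, NN) points (superior to deletion, which distorts
   the spectrum).
3. Time-domain (mean NN, SDNN, SDSD, RMSSD, pNN50) and Poincaré (SD1, SD2,
   SD1/SD2) measures on the irregular series; all but mean NN and the
   Poincaré descriptors are computed after linear detrending.
4. :func:`resample_nn` — cubic-spline fit evaluated on a 1 kHz grid, then
   decimated to 4 Hz; linear detrend; spectral estimation by Welch
   (Hamming, 256-sample windows, 50% overlap) and/or an order-16
   autoregressive model fitted with the Burg method.
5. :func:`band_powers` — trapezoidal band integration: LF 0.04-0.15 Hz,
   HF 0.15-0.4 Hz, normalized powers nLF/nHF (percent of LF+HF) and LF/HF.

Variance conventions: sample variance (1/(n-1)) for SDNN and SDSD;
population variance (1/n) inside the SD1/SD2 closed forms, under which
SD1 = RMSSD/sqrt(2) exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import welch as _welch
from statsmodels.regression.linear_model import burg as _burg

from .types import (
    AnalysisError,
    BeatSeries,
    HrvResult,
    HRV_MEASURES,
    NNSeries,
    ResampledNN,
    SpectralEstimate,
    SubsegmentSelection,
)

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
RESAMPLE_FS = 4.0
FINE_FS = 1000.0
AR_ORDER = 16
AR_NFREQ = 1024
WELCH_NPERSEG = 256


def rr_from_beats(bs: BeatSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(t_s, rr_ms, tainted) for consecutive beat pairs of one subsegment.

    ``t_s`` is the time of the terminating R peak; ``tainted`` marks intervals
    with an abnormal beat at either end.
    """
    if bs.n_beats < 2:
        raise AnalysisError("rr_from_beats: need at least two beats")
    t = bs.r_idx / bs.fs_hz
    rr_ms = np.diff(t) * 1000.0
    bad = (bs.labels[:-1] == "A") | (bs.labels[1:] == "A")
    return t[1:], rr_ms, bad


def edit_rr(
    t_s: np.ndarray,
    rr_ms: np.ndarray,
    tainted: np.ndarray,
    max_abnormal_frac: float = 0.05,
) -> NNSeries:
    """Replace tainted intervals by cubic-spline interpolation through clean points.

    Rejects the subsegment when the tainted-beat burden exceeds
    ``max_abnormal_frac`` (the caller must reselect a cleaner window).
    """
    t_s = np.asarray(t_s, dtype=float)
    rr_ms = np.asarray(rr_ms, dtype=float)
    tainted = np.asarray(tainted, dtype=bool)
    n = rr_ms.size
    if n < 4:
        raise AnalysisError("edit_rr: too few intervals")
    # tainted intervals come in pairs around each abnormal beat; halve to
    # express the burden as an abnormal-beat fraction
    frac = 0.5 * np.count_nonzero(tainted) / n
    if frac > max_abnormal_frac:
        raise AnalysisError(
            f"edit_rr: abnormal fraction {100 * frac:.1f}% exceeds "
            f"{100 * max_abnormal_frac:.0f}% editing limit"
        )
    nn = rr_ms.copy()
    if np.any(tainted):
        good = ~tainted
        if np.count_nonzero(good) < 4:
            raise AnalysisError("edit_rr: too few clean intervals to fit a spline")
        cs = CubicSpline(t_s[good], rr_ms[good])
        nn[tainted] = cs(t_s[tainted])
    return NNSeries(t_s=t_s, nn_ms=nn, edited=tainted.copy())


def resample_nn(
    nn: NNSeries,
    start_s: float | None = None,
    duration_s: float = 300.0,
    fine_fs: float = FINE_FS,
    out_fs: float = RESAMPLE_FS,
) -> ResampledNN:
    """Spline-fit the irregular NN sequence at 1 kHz, then decimate to 4 Hz."""
    if nn.t_s.size < 4:
        raise AnalysisError("resample_nn: need at least 4 intervals")
    if start_s is None:
        start_s = float(nn.t_s[0])
    cs = CubicSpline(nn.t_s, nn.nn_ms)
    n_fine = int(round(duration_s * fine_fs))
    t_fine = start_s + np.arange(n_fine) / fine_fs
    # clamp the evaluation grid to the data support; cubic extrapolation of
    # the edge polynomial can diverge over the sub-beat margins
    t_eval = np.clip(t_fine, nn.t_s[0], nn.t_s[-1])
    fine = cs(t_eval)
    step = int(round(fine_fs / out_fs))
    return ResampledNN(fs_hz=out_fs, values_ms=fine[::step], start_s=start_s)


def detrend_linear(x: NNSeries | ResampledNN | np.ndarray):
    """Remove the least-squares line; returns the same type as given."""
    if isinstance(x, NNSeries):
        vals = _detrend_vals(x.t_s, x.nn_ms)
        return NNSeries(t_s=x.t_s, nn_ms=vals, edited=x.edited.copy())
    if isinstance(x, ResampledNN):
        t = np.arange(x.values_ms.size) / x.fs_hz
        return ResampledNN(
            fs_hz=x.fs_hz,
            values_ms=_detrend_vals(t, x.values_ms),
            start_s=x.start_s,
            detrended=True,
        )
    arr = np.asarray(x, dtype=float)
    return _detrend_vals(np.arange(arr.size, dtype=float), arr)


def _detrend_vals(t: np.ndarray, v: np.ndarray) -> np.ndarray:
    if v.size < 2:
        raise AnalysisError("detrend_linear: need at least 2 points")
    coef = np.polynomial.polynomial.polyfit(t, v, 1)
    return v - np.polynomial.polynomial.polyval(t, coef)


def time_domain_measures(nn: NNSeries, detrend: bool = True) -> HrvResult:
    """Mean NN, SDNN, SDSD, RMSSD and pNN50.

    Mean NN always uses the raw values.  With ``detrend=True`` (the analysis
    default) the four variability measures are computed on the linearly
    detrended series; ``detrend=False`` applies the textbook definitions to
    the values as given.  pNN50 counts adjacent-pair differences exceeding
    50 ms (strict) against the total number of NN intervals.
    """
    if nn.nn_ms.size < 2:
        raise AnalysisError("time_domain_measures: need at least 2 intervals")
    vals = _detrend_vals(nn.t_s, nn.nn_ms) if detrend else nn.nn_ms
    d = np.diff(vals)
    res = HrvResult()
    res.mean_nn_ms = float(np.mean(nn.nn_ms))
    res.sdnn_ms = float(np.std(vals, ddof=1))
    res.sdsd_ms = float(np.std(d, ddof=1)) if d.size >= 2 else 0.0
    res.rmssd_ms = float(np.sqrt(np.mean(d**2)))
    res.pnn50_pct = 100.0 * float(np.count_nonzero(np.abs(d) > 50.0)) / nn.nn_ms.size
    return res


def pnn50_bruteforce(nn_ms: np.ndarray) -> float:
    """Direct pair count, the independent reference for pNN50."""
    nn_ms = np.asarray(nn_ms, dtype=float)
    count = sum(1 for a, b in zip(nn_ms[:-1], nn_ms[1:]) if abs(b - a) > 50.0)
    return 100.0 * count / nn_ms.size


def poincare_measures(nn: NNSeries) -> HrvResult:
    """SD1/SD2 Poincaré descriptors (population-variance closed forms).

    Computed on the non-detrended series: the Poincaré geometry is exempt
    from detrending, like mean NN.
    """
    v = nn.nn_ms
    if v.size < 3:
        raise AnalysisError("poincare_measures: need at least 3 intervals")
    d = np.diff(v)
    var_d = float(np.var(d))  # population variance
    var_v = float(np.var(v))
    res = HrvResult()
    res.sd1_ms = float(np.sqrt(var_d / 2.0))
    sd2_sq = 2.0 * var_v - var_d / 2.0
    res.sd2_ms = float(np.sqrt(max(sd2_sq, 0.0)))
    res.sd1_sd2 = res.sd1_ms / res.sd2_ms if res.sd2_ms > 0 else float("nan")
    return res


def estimate_psd(x: ResampledNN, method: str = "ar_burg") -> SpectralEstimate:
    """One-sided PSD (ms²/Hz) of a detrended 4 Hz NN series."""
    v = np.asarray(x.values_ms, dtype=float)
    fs = x.fs_hz
    if method == "welch":
        if v.size < WELCH_NPERSEG:
            raise AnalysisError(
                f"estimate_psd: series shorter than one Welch window "
                f"({v.size} < {WELCH_NPERSEG})"
            )
        f, p = _welch(
            v,
            fs=fs,
            window="hamming",
            nperseg=WELCH_NPERSEG,
            noverlap=WELCH_NPERSEG // 2,
            detrend="constant",
        )
        return SpectralEstimate(
            freqs_hz=f,
            psd_ms2_per_hz=p,
            method="welch",
            params={"nperseg": WELCH_NPERSEG, "noverlap": WELCH_NPERSEG // 2},
        )
    if method == "ar_burg":
        if v.size <= 2 * AR_ORDER:
            raise AnalysisError("estimate_psd: series too short for AR fit")
        f = np.linspace(0.0, fs / 2.0, AR_NFREQ)
        if np.ptp(v) == 0:
            return SpectralEstimate(
                freqs_hz=f,
                psd_ms2_per_hz=np.zeros_like(f),
                method="ar_burg",
                params={"order": AR_ORDER},
            )
        rho, sigma2 = _burg(v, order=AR_ORDER, demean=True)
        f = _ar_grid(rho, fs)
        k = np.arange(1, AR_ORDER + 1)
        den = np.abs(
            1.0 - np.sum(rho[:, None] * np.exp(-2j * np.pi * f[None, :] * k[:, None] / fs), axis=0)
        ) ** 2
        psd = 2.0 * sigma2 / fs / den  # one-sided
        return SpectralEstimate(
            freqs_hz=f,
            psd_ms2_per_hz=psd,
            method="ar_burg",
            params={"order": AR_ORDER, "nfreq": AR_NFREQ},
        )
    raise ValueError(f"estimate_psd: unknown method {method!r}")


def _ar_grid(rho: np.ndarray, fs: float) -> np.ndarray:
    """Frequency grid for evaluating an AR spectrum by trapezoidal integration.

    A uniform grid under-resolves the near-Lorentzian peaks of a
    high-resolution AR model, whose half-widths scale with the distance of
    the poles from the unit circle.  The uniform base grid is therefore
    augmented with points clustered around each pole frequency, spaced by an
    arctangent stretch of the pole's bandwidth so the peak's mass is captured
    regardless of how sharp it is.
    """
    base = np.linspace(0.0, fs / 2.0, AR_NFREQ)
    poles = np.roots(np.concatenate([[1.0], -rho]))
    extra = []
    u = np.tan(np.linspace(-0.498 * np.pi, 0.498 * np.pi, 201))
    for z in poles:
        r = np.abs(z)
        if r < 0.5:
            continue  # broad pole: the base grid resolves it
        f0 = np.angle(z) / (2 * np.pi) * fs
        if not 0.0 < f0 < fs / 2.0:
            continue
        bw = max((1.0 - r), 1e-12) * fs / (2 * np.pi)
        pts = f0 + bw * u
        extra.append(pts[(pts > 0.0) & (pts < fs / 2.0)])
    if extra:
        base = np.unique(np.concatenate([base] + extra))
    return base


def _band_integral(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi], edges interpolated."""
    inside = (f > lo) & (f < hi)
    fi = np.concatenate([[lo], f[inside], [hi]])
    pi = np.concatenate([
        [np.interp(lo, f, p)],
        p[inside],
        [np.interp(hi, f, p)],
    ])
    return float(np.trapezoid(pi, fi))


def band_powers(spec: SpectralEstimate) -> HrvResult:
    """LF/HF band powers, normalized powers and their ratio."""
    res = HrvResult(method=spec.method)
    lf = _band_integral(spec.freqs_hz, spec.psd_ms2_per_hz, *LF_BAND)
    hf = _band_integral(spec.freqs_hz, spec.psd_ms2_per_hz, *HF_BAND)
    res.lf_ms2 = lf
    res.hf_ms2 = hf
    tot = lf + hf
    if tot > 0:
        res.nlf_nu = 100.0 * lf / tot
        res.nhf_nu = 100.0 - res.nlf_nu  # exact complement
    res.lf_hf = lf / hf if hf > 0 else float("nan")
    return res


def hrv_for_segment(
    nn: NNSeries,
    start_s: float | None = None,
    method: str = "ar_burg",
    duration_s: float = 300.0,
) -> HrvResult:
    """All 13 measures for one edited subsegment."""
    td = time_domain_measures(nn, detrend=True)
    pc = poincare_measures(nn)
    rs = resample_nn(nn, start_s=start_s, duration_s=duration_s)
    spec = estimate_psd(detrend_linear(rs), method=method)
    fd = band_powers(spec)
    return HrvResult(
        mean_nn_ms=td.mean_nn_ms,
        sdnn_ms=td.sdnn_ms,
        sdsd_ms=td.sdsd_ms,
        rmssd_ms=td.rmssd_ms,
        pnn50_pct=td.pnn50_pct,
        sd1_ms=pc.sd1_ms,
        sd2_ms=pc.sd2_ms,
        sd1_sd2=pc.sd1_sd2,
        lf_ms2=fd.lf_ms2,
        hf_ms2=fd.hf_ms2,
        nlf_nu=fd.nlf_nu,
        nhf_nu=fd.nhf_nu,
        lf_hf=fd.lf_hf,
        method=method,
    )


def hrv_for_patient(
    segments: list[tuple[SubsegmentSelection, NNSeries]],
    method: str = "ar_burg",
    duration_s: float = 300.0,
) -> tuple[list[HrvResult], dict[str, float]]:
    """Per-segment results plus the per-patient median of each measure."""
    accepted = [(sel, nn) for sel, nn in segments if sel.accepted]
    if not accepted:
        raise AnalysisError("hrv_for_patient: no accepted subsegments")
    results = []
    for sel, nn in accepted:
        r = hrv_for_segment(nn, start_s=sel.start_clock_s, method=method,
                            duration_s=duration_s)
        r.segment_index = sel.segment_index
        results.append(r)
    medians = {
        k: float(np.nanmedian([getattr(r, k) for r in results])) for k in HRV_MEASURES
    }
    return results, medians
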