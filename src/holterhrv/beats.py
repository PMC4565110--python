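"""QRS detection, Q/T peak location, beat classification, ST screening.

The detector is Pan-Tompkins style: 5-15 Hz band-pass, squared derivative,
150 ms moving-window integration, adaptive threshold with a 200 ms refractory
period.  Q is the signal minimum in a fixed window before R; T the dominant
extremum in an RR-adaptive window after R.

Classification marks a beat abnormal (label ``A``) when any of three rules
fires: QRS width above 1.5x the running median of normal widths, RR outside
[0.8, 1.2]x the running median of the last 8 normal RR intervals, or
correlation with the running normal-beat template below 0.9.  Q/T locations
are retained only for normal beats; those of abnormal beats are unreliable.

ST-segment screening is a deliberately simple, documented operator standing
in for proprietary Holter software: ST level = mean amplitude over
[R+60, R+80) ms minus the PQ baseline (mean over [R-120, R-80) ms); a beat is
flagged when |level| exceeds a threshold (default 100 µV).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, filtfilt, find_peaks

from .types import AnalysisError, BeatSeries, BeatSummary, EcgRecord

MIN_RECORD_S = 10.0
REFRACTORY_S = 0.200
SNIPPET_HALF_S = 0.100  # morphology window R +/- 100 ms


def _bandpass(x: np.ndarray, fs: float, lo: float = 5.0, hi: float = 15.0) -> np.ndarray:
    b, a = butter(2, [lo / (fs / 2), hi / (fs / 2)], btype="band")
    return filtfilt(b, a, x)


def _qrs_width_ms(bp: np.ndarray, r: int, fs: float) -> float:
    """Width of the band-passed QRS complex at 25% of its local peak amplitude."""
    half = int(round(0.125 * fs))
    lo, hi = max(0, r - half), min(bp.size, r + half + 1)
    seg = np.abs(bp[lo:hi])
    peak = seg.max()
    if peak <= 0:
        return np.nan
    above = seg >= 0.25 * peak
    return 1000.0 * np.count_nonzero(above) / fs


def detect_beats(rec: EcgRecord, lead: str) -> BeatSeries:
    """Locate R, Q and T peaks on one lead.

    Returns an all-``N``-labelled series; run :func:`classify_beats` next.
    A flat-line lead yields an empty series with a warning.
    """
    if rec.duration_s < MIN_RECORD_S:
        raise AnalysisError(
            f"record too short for beat detection ({rec.duration_s:.1f} s < {MIN_RECORD_S} s)"
        )
    x = rec.lead(lead)
    fs = rec.fs_hz
    if np.ptp(x) == 0:
        warnings.warn(f"lead {lead}: flat line, no beats detected")
        return BeatSeries(lead=lead, fs_hz=fs, r_idx=np.empty(0, dtype=np.int64),
                          start_clock_s=rec.start_clock_s)

    bp = _bandpass(x, fs)
    det = np.gradient(bp) ** 2
    det = uniform_filter1d(det, size=max(3, int(round(0.150 * fs))))

    dist = max(1, int(round(REFRACTORY_S * fs)))
    cand, _ = find_peaks(det, distance=dist)
    if cand.size == 0:
        warnings.warn(f"lead {lead}: no QRS candidates found")
        return BeatSeries(lead=lead, fs_hz=fs, r_idx=np.empty(0, dtype=np.int64),
                          start_clock_s=rec.start_clock_s)
    # adaptive threshold: a fixed fraction of the upper-quartile candidate height
    thr = 0.20 * np.percentile(det[cand], 90)
    peaks = cand[det[cand] >= thr]

    # refine each detection to the local extremum of the band-passed signal
    half = int(round(0.100 * fs))
    r_idx = []
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        r_idx.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    r_idx = np.asarray(sorted(set(r_idx)), dtype=np.int64)
    # enforce refractory after refinement
    if r_idx.size:
        keep = [0]
        for i in range(1, r_idx.size):
            if r_idx[i] - r_idx[keep[-1]] >= dist:
                keep.append(i)
            elif det[r_idx[i]] > det[r_idx[keep[-1]]]:
                keep[-1] = i
        r_idx = r_idx[keep]

    n = r_idx.size
    q_idx = np.full(n, -1, dtype=np.int64)
    t_idx = np.full(n, -1, dtype=np.int64)
    widths = np.full(n, np.nan)
    rr = np.diff(r_idx) / fs
    med_rr = float(np.median(rr)) if rr.size else 0.8
    baseline = float(np.median(x))

    snip_half = int(round(SNIPPET_HALF_S * fs))
    snippets = np.zeros((n, 2 * snip_half + 1))

    for i, r in enumerate(r_idx):
        widths[i] = _qrs_width_ms(bp, r, fs)
        # Q: minimum in [R-80 ms, R-10 ms)
        qlo, qhi = r - int(round(0.080 * fs)), r - int(round(0.010 * fs))
        if qlo >= 0 and qhi > qlo:
            q_idx[i] = qlo + int(np.argmin(x[qlo:qhi]))
        # T: dominant extremum in [R+120 ms, R+0.6*RR)
        rr_next = rr[i] if i < rr.size else med_rr
        tlo = r + int(round(0.120 * fs))
        thi = r + int(round(0.6 * rr_next * fs))
        if thi > tlo and thi <= x.size:
            seg = x[tlo:thi] - baseline
            t_idx[i] = tlo + int(np.argmax(np.abs(seg)))
        lo, hi = r - snip_half, r + snip_half + 1
        if lo >= 0 and hi <= x.size:
            snippets[i] = x[lo:hi]

    return BeatSeries(
        lead=lead,
        fs_hz=fs,
        r_idx=r_idx,
        q_idx=q_idx,
        t_idx=t_idx,
        start_clock_s=rec.start_clock_s,
        qrs_width_ms=widths,
        snippets=snippets,
    )


def classify_beats(
    bs: BeatSeries,
    width_factor: float = 1.5,
    rr_low: float = 0.8,
    rr_high: float = 1.2,
    corr_min: float = 0.9,
) -> BeatSeries:
    """Label each beat ``N`` or ``A`` by width, RR and template-correlation rules."""
    n = bs.n_beats
    if n == 0:
        raise AnalysisError("classify_beats: no detected beats")
    labels = np.full(n, "N", dtype="<U1")
    rr = np.diff(bs.r_idx) / bs.fs_hz

    normal_rr: list[float] = []
    normal_w: list[float] = []
    template: np.ndarray | None = None
    n_templ = 0

    have_morph = bs.snippets is not None

    for i in range(n):
        abnormal = False
        w = bs.qrs_width_ms[i]
        if normal_w and np.isfinite(w) and w > width_factor * np.median(normal_w):
            abnormal = True
        if i > 0 and len(normal_rr) >= 3:
            med = np.median(normal_rr[-8:])
            if rr[i - 1] < rr_low * med or rr[i - 1] > rr_high * med:
                abnormal = True
        if not abnormal and have_morph and template is not None:
            s = bs.snippets[i]
            if np.std(s) > 0 and np.std(template) > 0:
                c = float(np.corrcoef(s, template)[0, 1])
                if c < corr_min:
                    abnormal = True
        if abnormal:
            labels[i] = "A"
        else:
            if i > 0:
                normal_rr.append(float(rr[i - 1]))
            if np.isfinite(w):
                normal_w.append(float(w))
            if have_morph:
                template = (
                    bs.snippets[i].copy()
                    if template is None
                    else (template * n_templ + bs.snippets[i]) / (n_templ + 1)
                )
                n_templ = min(n_templ + 1, 16)

    q_idx = np.where(labels == "N", bs.q_idx, -1)
    t_idx = np.where(labels == "N", bs.t_idx, -1)
    return BeatSeries(
        lead=bs.lead,
        fs_hz=bs.fs_hz,
        r_idx=bs.r_idx,
        q_idx=q_idx,
        t_idx=t_idx,
        labels=labels,
        st_dev=bs.st_dev,
        start_clock_s=bs.start_clock_s,
        qrs_width_ms=bs.qrs_width_ms,
        snippets=bs.snippets,
    )


def flag_st_deviation(
    rec: EcgRecord, bs: BeatSeries, threshold_uV: float = 100.0
) -> BeatSeries:
    """Flag normal beats whose ST level deviates from the PQ baseline."""
    x = rec.lead(bs.lead)
    fs = bs.fs_hz
    st = np.zeros(bs.n_beats, dtype=bool)
    b0, b1 = int(round(0.120 * fs)), int(round(0.080 * fs))
    s0, s1 = int(round(0.060 * fs)), int(round(0.080 * fs))
    for i, r in enumerate(bs.r_idx):
        if bs.labels[i] != "N":
            continue
        blo, bhi = r - b0, r - b1
        slo, shi = r + s0, r + s1
        if blo < 0 or shi > x.size or shi <= slo or bhi <= blo:
            continue
        level = float(np.mean(x[slo:shi]) - np.mean(x[blo:bhi]))
        st[i] = abs(level) >= threshold_uV
    out = bs.subset(np.arange(bs.n_beats))
    out.st_dev = st
    return out


LEAD_PRIORITY = ("II", "I", "V6")


def select_lead(candidates: list[BeatSeries]) -> str:
    """Pick the analysis lead: most detected beats, fewest abnormal, fixed priority."""
    if not candidates:
        raise AnalysisError("select_lead: empty candidate list")

    def prio(name: str) -> int:
        return LEAD_PRIORITY.index(name) if name in LEAD_PRIORITY else len(LEAD_PRIORITY)

    best = min(
        candidates,
        key=lambda b: (-b.n_beats, int(np.sum(b.labels == "A")), prio(b.lead)),
    )
    return best.lead


def summarize_beats(bs: BeatSeries) -> BeatSummary:
    """Count normal/abnormal/ST-flagged beats with the reporting conventions.

    Abnormal percentage uses all beats (N+A) as denominator; ST percentage
    uses normal beats only.  Percentages are rounded to 3 decimals.
    """
    if bs.n_beats == 0:
        raise AnalysisError("summarize_beats: zero beats")
    n_a = int(np.sum(bs.labels == "A"))
    n_n = int(np.sum(bs.labels == "N"))
    n_st = int(np.sum(bs.st_dev & (bs.labels == "N")))
    return summary_from_counts(n_n, n_a, n_st)


def summary_from_counts(n_normal: int, n_abnormal: int, n_st: int) -> BeatSummary:
    """Apply the percentage conventions to externally supplied beat counts."""
    if n_normal + n_abnormal == 0:
        raise AnalysisError("summary_from_counts: zero beats")
    pct_a = round(100.0 * n_abnormal / (n_normal + n_abnormal), 3)
    pct_st = round(100.0 * n_st / n_normal, 3) if n_normal else float("nan")
    return BeatSummary(n_normal=n_normal, n_abnormal=n_abnormal, pct_abnormal=pct_a,
                       n_st=n_st, pct_st=pct_st)
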