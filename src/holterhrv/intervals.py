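"""Peak-to-peak QT intervals and their Bazett-corrected values.

ppQT is the interval from the Q peak to the T peak of a normal beat — peak
locations are far more reliably detectable than Q-wave onset or T-wave end.
The corrected value follows the common Bazett convention,

    ppQTc [ms] = ppQT [ms] / sqrt(RR [s]),

with RR the normal-to-normal interval ending at the beat's R peak (both
neighbours normal).
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import AnalysisError, BeatSeries, QtSeries


def compute_ppqtc(bs: BeatSeries) -> QtSeries:
    """Per-beat ppQT/ppQTc over a classified beat series.

    Beats lacking a Q or T location, labelled abnormal, or whose preceding
    beat is abnormal are skipped and counted in ``n_skipped``.
    """
    fs = bs.fs_hz
    ppqt, ppqtc, rrs = [], [], []
    skipped = 0
    for i in range(1, bs.n_beats):
        ok = (
            bs.labels[i] == "N"
            and bs.labels[i - 1] == "N"
            and bs.q_idx[i] >= 0
            and bs.t_idx[i] >= 0
        )
        if not ok:
            skipped += 1
            continue
        rr = (bs.r_idx[i] - bs.r_idx[i - 1]) / fs
        qt_ms = (bs.t_idx[i] - bs.q_idx[i]) / fs * 1000.0
        if qt_ms <= 0 or rr <= 0:
            skipped += 1
            continue
        ppqt.append(qt_ms)
        ppqtc.append(qt_ms / np.sqrt(rr))
        rrs.append(rr)
    if not ppqt:
        warnings.warn("compute_ppqtc: no eligible beats (series unusable for QT analysis)")
    return QtSeries(
        ppqt_ms=np.asarray(ppqt),
        ppqtc_ms=np.asarray(ppqtc),
        rr_s=np.asarray(rrs),
        n_skipped=skipped,
    )


def summarize_ppqtc(qs: QtSeries) -> float:
    """Median ppQTc over all eligible beats (mean-of-middle for even counts)."""
    if qs.ppqtc_ms.size == 0:
        raise AnalysisError("summarize_ppqtc: empty QT series")
    return float(np.median(qs.ppqtc_ms))
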