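"""Night-window extraction and escalating-threshold subsegment selection.

The analysis window defaults to the night-time interval 00:00-04:00, when
patient activity is minimal and the signal most stationary.  The window is
divided into 20-min segments (twelve for the full 4-h window) and from each
segment the earliest 5-min subsegment is chosen that (a) contains less than
``threshold`` percent abnormal beats and (b) starts at least 10 min after the
end of the previously accepted subsegment.  The threshold starts at 1% and
escalates in 1% steps up to 5%; if no window qualifies at 5% the segment is
marked not accepted and downstream analysis omits it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import AnalysisError, BeatSeries, EcgRecord, SubsegmentSelection

NIGHT_WINDOW_S = (0.0, 4 * 3600.0)  # clock seconds since midnight


def extract_night_window(
    bs: BeatSeries,
    rec: EcgRecord | None = None,
    window_s: tuple[float, float] = NIGHT_WINDOW_S,
) -> BeatSeries:
    """Keep beats whose clock time falls in ``[window_start, window_end)``.

    Beat indices are re-based so that sample 0 corresponds to the window
    start; the returned series carries the window start as its clock origin.
    The parent record (or the beat series itself) must span the whole window.
    """
    w0, w1 = window_s
    if w1 <= w0:
        raise AnalysisError("night window: end must be after start")
    fs = bs.fs_hz
    start = bs.start_clock_s
    if rec is not None:
        end = start + rec.duration_s
    elif bs.n_beats:
        end = start + bs.r_idx[-1] / fs
    else:
        end = start
    # first occurrence of the window start at/after the record start
    k = np.ceil((start - w0) / 86400.0)
    abs_w0 = w0 + 86400.0 * k
    abs_w1 = abs_w0 + (w1 - w0)
    covers = abs_w0 >= start and abs_w1 <= end
    if not covers and abs_w0 + 86400.0 <= end:  # window may recur next midnight
        abs_w0 += 86400.0
        abs_w1 += 86400.0
        covers = abs_w0 >= start and abs_w1 <= end
    inside = start >= abs_w0 and end <= abs_w1  # record wholly inside the window
    if not covers and not inside:
        raise AnalysisError(
            f"record does not cover the analysis window "
            f"[{w0 / 3600:.2f}h, {w1 / 3600:.2f}h) "
            f"(record spans clock {start:.0f}s to {end:.0f}s)"
        )
    t_clock = start + bs.r_idx / fs
    mask = (t_clock >= abs_w0) & (t_clock < abs_w1)
    out = bs.subset(mask)
    offset = max(0, int(round((abs_w0 - start) * fs)))
    out.r_idx = out.r_idx - offset
    out.q_idx = np.where(out.q_idx >= 0, out.q_idx - offset, -1)
    out.t_idx = np.where(out.t_idx >= 0, out.t_idx - offset, -1)
    out.start_clock_s = w0 if covers else bs.start_clock_s
    return out


@dataclass
class SelectionParams:
    """Geometry of the selection scan (durations in seconds)."""

    n_segments: int = 12
    segment_s: float = 1200.0
    sub_s: float = 300.0
    gap_s: float = 600.0
    max_threshold_pct: int = 5
    scan_step_s: float = 1.0


def _window_fraction(r_rel: np.ndarray, abnormal: np.ndarray, t0: float, t1: float):
    """(n_beats, n_abnormal, abnormal fraction) for beats with R in [t0, t1)."""
    i0, i1 = np.searchsorted(r_rel, [t0, t1], side="left")
    n = int(i1 - i0)
    if n == 0:
        return 0, 0, 0.0
    na = int(abnormal[i1] - abnormal[i0])
    return n, na, na / n


def select_subsegments(
    bs: BeatSeries, params: SelectionParams | None = None
) -> list[SubsegmentSelection]:
    """Choose one subsegment per segment by the escalating-threshold scan.

    ``bs`` must be the re-based night-window series (beat time 0 = window
    start).  Within each segment every candidate start on a 1-s grid is
    examined in order; the first start meeting the abnormal-fraction bound
    (strict ``<``) and the spacing constraint wins, at the smallest feasible
    threshold.  Spacing is measured to the previously *accepted* subsegment.
    """
    p = params or SelectionParams()
    r_rel = bs.r_idx / bs.fs_hz
    abnormal_cum = np.concatenate([[0], np.cumsum(bs.labels == "A")])

    selections: list[SubsegmentSelection] = []
    prev_end: float | None = None
    for seg in range(p.n_segments):
        seg_start = seg * p.segment_s
        seg_end = seg_start + p.segment_s
        starts = np.arange(seg_start, seg_end - p.sub_s + 1e-9, p.scan_step_s)
        found = None
        for thr in range(1, p.max_threshold_pct + 1):
            for s in starts:
                if prev_end is not None and s < prev_end + p.gap_s:
                    continue
                n, na, frac = _window_fraction(r_rel, abnormal_cum, s, s + p.sub_s)
                if frac * 100.0 < thr:
                    found = (s, thr, n, na)
                    break
            if found:
                break
        if found:
            s, thr, n, na = found
            selections.append(
                SubsegmentSelection(
                    segment_index=seg,
                    start_clock_s=bs.start_clock_s + s,
                    end_clock_s=bs.start_clock_s + s + p.sub_s,
                    threshold_used=thr,
                    n_beats=n,
                    n_abnormal=na,
                    accepted=True,
                )
            )
            prev_end = s + p.sub_s
        else:
            selections.append(
                SubsegmentSelection(
                    segment_index=seg,
                    start_clock_s=bs.start_clock_s + seg_start,
                    end_clock_s=bs.start_clock_s + seg_start + p.sub_s,
                    threshold_used=None,
                    n_beats=0,
                    n_abnormal=0,
                    accepted=False,
                )
            )
    return selections


def beats_in_selection(bs: BeatSeries, sel: SubsegmentSelection) -> BeatSeries:
    """Beats of the night-window series whose R peak lies inside a selection."""
    t = bs.start_clock_s + bs.r_idx / bs.fs_hz
    return bs.subset((t >= sel.start_clock_s) & (t < sel.end_clock_s))
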