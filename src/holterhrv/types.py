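"""Core containers shared by every pipeline stage.

Conventions used throughout the package (stated once, asserted everywhere):

* signal samples are in microvolts (µV); voltage/current in SI units (V, A);
* time is in seconds; sample indices are 0-based; windows are half-open
  ``[start, end)``;
* clock time-of-day is represented as seconds since midnight (float); the
  first sample of a record carries its ``start_clock_s``;
* missing Q/T locations are encoded as ``-1`` in integer index arrays;
* medians of even-length sets are the mean of the two middle values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Invalid simulation or run configuration; message names the field."""


class FormatError(ValueError):
    """Malformed input file (missing column, non-uniform sampling, ...)."""


class AnalysisError(ValueError):
    """A stage precondition is not met (record too short, no beats, ...)."""


def parse_clock(clock: str | float | int) -> float:
    """Convert ``"HH:MM[:SS]"`` (or a number of seconds) to seconds since midnight."""
    if isinstance(clock, (int, float)):
        s = float(clock)
    else:
        parts = clock.split(":")
        if len(parts) not in (2, 3):
            raise ConfigurationError(f"start_clock: cannot parse clock string {clock!r}")
        h, m = int(parts[0]), int(parts[1])
        sec = float(parts[2]) if len(parts) == 3 else 0.0
        s = h * 3600.0 + m * 60.0 + sec
    return s % 86400.0


def format_clock(seconds: float) -> str:
    s = seconds % 86400.0
    h = int(s // 3600)
    m = int((s % 3600) // 60)
    sec = s % 60
    return f"{h:02d}:{m:02d}:{sec:06.3f}"


@dataclass
class EcgRecord:
    """Multi-lead ECG waveform with sampling rate and start time-of-day.

    ``signals`` is a ``(n_leads, n_samples)`` float array in µV, row order
    matching ``lead_names``.
    """

    signals: np.ndarray
    fs_hz: float
    lead_names: list[str]
    start_clock_s: float = 0.0
    patient_id: str = ""
    session: str = ""  # "before" | "after" | ""

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.fs_hz <= 0:
            raise ConfigurationError("fs_hz: must be > 0")
        if len(self.lead_names) != self.signals.shape[0]:
            raise FormatError(
                f"lead_names: {len(self.lead_names)} names for {self.signals.shape[0]} signal rows"
            )
        if len(set(self.lead_names)) != len(self.lead_names):
            raise FormatError("lead_names: duplicate lead name")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def lead(self, name: str) -> np.ndarray:
        if name not in self.lead_names:
            raise FormatError(f"lead: {name!r} not in record (has {self.lead_names})")
        return self.signals[self.lead_names.index(name)]


@dataclass
class GroundTruth:
    """Oracle annotations emitted by the ECG simulator.

    ``q_times_s``/``t_times_s`` are NaN for abnormal beats, whose Q/T peaks
    are not meaningful analysis inputs.
    """

    r_times_s: np.ndarray
    q_times_s: np.ndarray
    t_times_s: np.ndarray
    labels: np.ndarray  # unicode 'N' / 'A' per beat
    st_flags: np.ndarray  # bool per beat

    def __post_init__(self) -> None:
        self.r_times_s = np.asarray(self.r_times_s, dtype=float)
        if np.any(np.diff(self.r_times_s) <= 0):
            raise ValueError("r_times_s must be strictly increasing")
        n = self.r_times_s.size
        for name in ("q_times_s", "t_times_s", "labels", "st_flags"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != beat count")


@dataclass
class BeatSeries:
    """Per-beat Q/R/T locations, normal/abnormal labels and ST flags for one lead."""

    lead: str
    fs_hz: float
    r_idx: np.ndarray
    q_idx: np.ndarray = None  # -1 where absent
    t_idx: np.ndarray = None
    labels: np.ndarray = None  # 'N' / 'A'
    st_dev: np.ndarray = None  # bool
    start_clock_s: float = 0.0
    qrs_width_ms: np.ndarray = None
    snippets: np.ndarray | None = None  # (n_beats, w) morphology windows, detector-internal

    def __post_init__(self) -> None:
        self.r_idx = np.asarray(self.r_idx, dtype=np.int64)
        n = self.r_idx.size
        if n and np.any(np.diff(self.r_idx) <= 0):
            raise ValueError("r_idx must be strictly increasing")
        if self.q_idx is None:
            self.q_idx = np.full(n, -1, dtype=np.int64)
        if self.t_idx is None:
            self.t_idx = np.full(n, -1, dtype=np.int64)
        if self.labels is None:
            self.labels = np.full(n, "N", dtype="<U1")
        if self.st_dev is None:
            self.st_dev = np.zeros(n, dtype=bool)
        if self.qrs_width_ms is None:
            self.qrs_width_ms = np.full(n, np.nan)
        for name in ("q_idx", "t_idx", "labels", "st_dev", "qrs_width_ms"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of beats")

    @property
    def n_beats(self) -> int:
        return self.r_idx.size

    @property
    def r_times_s(self) -> np.ndarray:
        """Beat times in seconds from the first sample of the parent record."""
        return self.r_idx / self.fs_hz

    @property
    def r_clock_s(self) -> np.ndarray:
        """Beat times as clock seconds since midnight (may exceed 86400 across midnight)."""
        return self.start_clock_s + self.r_idx / self.fs_hz

    def subset(self, mask_or_idx) -> "BeatSeries":
        sel = np.asarray(mask_or_idx)
        return BeatSeries(
            lead=self.lead,
            fs_hz=self.fs_hz,
            r_idx=self.r_idx[sel],
            q_idx=self.q_idx[sel],
            t_idx=self.t_idx[sel],
            labels=self.labels[sel],
            st_dev=self.st_dev[sel],
            start_clock_s=self.start_clock_s,
            qrs_width_ms=self.qrs_width_ms[sel],
            snippets=None if self.snippets is None else self.snippets[sel],
        )


@dataclass
class BeatSummary:
    n_normal: int
    n_abnormal: int
    pct_abnormal: float
    n_st: int
    pct_st: float


@dataclass
class SubsegmentSelection:
    """One 5-min analysis window chosen inside a 20-min parent segment."""

    segment_index: int
    start_clock_s: float
    end_clock_s: float
    threshold_used: int | None  # percent, None when not accepted
    n_beats: int
    n_abnormal: int
    accepted: bool


@dataclass
class QtSeries:
    """Per-normal-beat peak-to-peak QT intervals and Bazett-corrected values."""

    ppqt_ms: np.ndarray
    ppqtc_ms: np.ndarray
    rr_s: np.ndarray
    n_skipped: int = 0


@dataclass
class NNSeries:
    """Normal-to-normal interval sequence; ``t_s`` is the terminating beat time."""

    t_s: np.ndarray
    nn_ms: np.ndarray
    edited: np.ndarray  # bool, True where the interval value was interpolated

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.nn_ms = np.asarray(self.nn_ms, dtype=float)
        self.edited = np.asarray(self.edited, dtype=bool)
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("t_s must be strictly increasing")
        if self.t_s.size != self.nn_ms.size or self.t_s.size != self.edited.size:
            raise ValueError("t_s, nn_ms, edited must have equal length")


@dataclass
class ResampledNN:
    """Equidistantly resampled NN curve (default 4 Hz) for spectral analysis."""

    fs_hz: float
    values_ms: np.ndarray
    start_s: float = 0.0
    detrended: bool = False


@dataclass
class SpectralEstimate:
    freqs_hz: np.ndarray
    psd_ms2_per_hz: np.ndarray
    method: str  # "welch" | "ar_burg"
    params: dict = field(default_factory=dict)


#: Canonical order of the 13 HRV measures reported per segment/patient.
HRV_MEASURES = (
    "mean_nn_ms",
    "sdnn_ms",
    "sdsd_ms",
    "rmssd_ms",
    "pnn50_pct",
    "sd1_ms",
    "sd2_ms",
    "sd1_sd2",
    "lf_ms2",
    "hf_ms2",
    "nlf_nu",
    "nhf_nu",
    "lf_hf",
)


@dataclass
class HrvResult:
    """The 13 HRV measures for one 5-min subsegment (NaN marks undefined ratios)."""

    mean_nn_ms: float = np.nan
    sdnn_ms: float = np.nan
    sdsd_ms: float = np.nan
    rmssd_ms: float = np.nan
    pnn50_pct: float = np.nan
    sd1_ms: float = np.nan
    sd2_ms: float = np.nan
    sd1_sd2: float = np.nan
    lf_ms2: float = np.nan
    hf_ms2: float = np.nan
    nlf_nu: float = np.nan
    nhf_nu: float = np.nan
    lf_hf: float = np.nan
    method: str = ""
    segment_index: int | None = None

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in HRV_MEASURES}


@dataclass
class PulseTrainRecord:
    """Recorded voltage/current time course for one train of EP pulses."""

    time_s: np.ndarray
    voltage_v: np.ndarray
    current_a: np.ndarray
    train_id: int = 0
    tumor_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.voltage_v = np.asarray(self.voltage_v, dtype=float)
        self.current_a = np.asarray(self.current_a, dtype=float)
        if not (self.time_s.size == self.voltage_v.size == self.current_a.size):
            raise FormatError("time_s, voltage_v, current_a must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise FormatError(
                f"time_s not strictly increasing within train {self.train_id}"
            )


@dataclass
class TumorDose:
    tumor_id: str
    n_pulses: int
    avg_voltage_v: float
    avg_current_a: float
    energy_j: float


@dataclass
class PatientDose:
    patient_id: str
    tumors: list[TumorDose]
    total_energy_j: float
    max_avg_voltage_v: float
    max_avg_current_a: float
    total_pulses: int


@dataclass
class ComparisonRow:
    """One row of the before/after comparison table."""

    parameter: str
    median_change: float
    pct25: float
    pct75: float
    p_value: float
    n: int = 0


@dataclass
class RegressionRow:
    delta_parameter: str
    dose_parameter: str
    slope: float
    r: float
    p_value: float
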