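"""Ground-truthed synthetic Holter ECG and electroporation-pulse waveforms.

The ECG generator is a parametric stand-in for an ambulatory 9-lead Holter
recording: each heartbeat is a sum-of-Gaussians PQRST template placed at beat
times driven by a modulated RR sequence

    RR(t) = mean_rr + a_lf * sin(2*pi*f_lf*t) + a_hf * sin(2*pi*f_hf*t) + jitter,

with the low-frequency (0.04-0.15 Hz) and high-frequency (0.15-0.4 Hz) terms
providing controllable LF/HF spectral content.  Because template peak
locations are known analytically, the emitted :class:`~holterhrv.types.GroundTruth`
is an exact oracle for the beat detector and classifier.

Abnormal (premature-ventricular-like) beats are morphologically distinct:
widened QRS (x2.5), inverted T, no P wave, preceding RR shortened by 20-40%
and the following RR lengthened so the two-beat span is preserved
(compensatory pause).

The EP generator emits trains of rectangular voltage/current pulses into a
resistive load, with optional linear amplitude droop across each pulse and
relative broadband noise.  Each pulse spans ``[t0, t0 + pulse_us]`` inclusive
of both edge samples so that trapezoidal integration of V*I recovers the
ideal energy exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import ConfigurationError, EcgRecord, GroundTruth, PulseTrainRecord, parse_clock

#: Default 9-lead ambulatory montage.
DEFAULT_LEADS = ["I", "II", "III", "aVR", "aVL", "aVF", "V1", "V3", "V6"]

#: Per-lead multiplicative scaling of the base (lead II) template.  Signs and
#: magnitudes are a coarse caricature of real lead projections; they only need
#: to give leads I/II/V6 the large R amplitudes the analysis selects for.
LEAD_SCALE = {
    "I": 0.70,
    "II": 1.00,
    "III": 0.50,
    "aVR": -0.85,
    "aVL": 0.35,
    "aVF": 0.80,
    "V1": -0.45,
    "V3": 0.90,
    "V6": 0.95,
}

# Base PQRST template: (amplitude µV, center ms relative to R, sigma ms)
_NORMAL_WAVES = (
    (120.0, -180.0, 25.0),   # P
    (-150.0, -40.0, 10.0),   # Q
    (1000.0, 0.0, 12.0),     # R
    (-250.0, 40.0, 10.0),    # S
    (350.0, 250.0, 40.0),    # T
)
# Ectopic: no P, QRS widened x2.5, inverted/wider T.
_ECTOPIC_WAVES = (
    (-180.0, -40.0 * 2.5, 25.0),
    (1150.0, 0.0, 30.0),
    (-300.0, 45.0 * 2.5, 30.0),
    (-350.0, 280.0, 50.0),
)

Q_OFFSET_S = -0.040  # analytic Q-peak location relative to R
T_OFFSET_S = 0.250   # analytic T-peak location relative to R


@dataclass
class EcgSimConfig:
    """Parameters of one simulated Holter session.

    ``lf_mod``/``hf_mod`` are ``(freq_hz, amplitude_ms)`` sinusoidal RR
    modulations; ``rr_jitter_ms`` is the RMS of additive white RR jitter
    (default 5 ms, a realistic residual beat-to-beat variability).
    ``st_offset_uV`` shifts the ST level of a fraction ``st_fraction`` of
    beats.  ``ectopic_pattern`` is ``"uniform"`` or
    ``("clustered", start_s, end_s)``.
    """

    duration_s: float = 600.0
    fs_hz: float = 200.0
    leads: list[str] = field(default_factory=lambda: list(DEFAULT_LEADS))
    start_clock: str | float = "00:00:00"
    mean_rr_ms: float = 800.0
    lf_mod: tuple[float, float] = (0.10, 0.0)
    hf_mod: tuple[float, float] = (0.25, 0.0)
    rr_jitter_ms: float = 5.0
    ectopic_rate: float = 0.0
    ectopic_pattern: str | tuple = "uniform"
    noise_uV: float = 0.0
    st_offset_uV: float = 0.0
    st_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        # tolerate YAML/CLI strings for numeric fields
        for name in ("duration_s", "fs_hz", "mean_rr_ms", "rr_jitter_ms",
                     "ectopic_rate", "noise_uV", "st_offset_uV", "st_fraction"):
            setattr(self, name, float(getattr(self, name)))
        self.seed = int(self.seed)
        self.lf_mod = (float(self.lf_mod[0]), float(self.lf_mod[1]))
        self.hf_mod = (float(self.hf_mod[0]), float(self.hf_mod[1]))

    def validate(self) -> None:
        if self.fs_hz <= 0:
            raise ConfigurationError("fs_hz: must be > 0")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s: must be > 0")
        if not self.leads:
            raise ConfigurationError("leads: must name at least one lead")
        unknown = [ld for ld in self.leads if ld not in LEAD_SCALE]
        if unknown:
            raise ConfigurationError(f"leads: unknown lead(s) {unknown}")
        if not 0.0 <= self.ectopic_rate <= 1.0:
            raise ConfigurationError("ectopic_rate: must be in [0, 1]")
        for name in ("lf_mod", "hf_mod"):
            f, a = getattr(self, name)
            if a < 0:
                raise ConfigurationError(f"{name}: amplitude must be >= 0")
            if a > 0 and f <= 0:
                raise ConfigurationError(f"{name}: frequency must be > 0")
        if self.rr_jitter_ms < 0:
            raise ConfigurationError("rr_jitter_ms: must be >= 0")
        if self.noise_uV < 0:
            raise ConfigurationError("noise_uV: must be >= 0")
        if not 0.0 <= self.st_fraction <= 1.0:
            raise ConfigurationError("st_fraction: must be in [0, 1]")
        amax = max(self.lf_mod[1], self.hf_mod[1])
        if self.mean_rr_ms <= 2 * amax:
            raise ConfigurationError(
                "mean_rr_ms: must exceed twice the largest modulation amplitude"
            )
        if isinstance(self.ectopic_pattern, (tuple, list)):
            if len(self.ectopic_pattern) != 3 or self.ectopic_pattern[0] != "clustered":
                raise ConfigurationError(
                    "ectopic_pattern: expected 'uniform' or ('clustered', start_s, end_s)"
                )
        elif self.ectopic_pattern != "uniform":
            raise ConfigurationError(
                "ectopic_pattern: expected 'uniform' or ('clustered', start_s, end_s)"
            )


def _rr_sequence(cfg: EcgSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Beat times (s) spanning the record, leaving template margins at both ends."""
    f_lf, a_lf = cfg.lf_mod
    f_hf, a_hf = cfg.hf_mod
    t = 0.4  # leave room for the P wave of the first beat
    t_end = cfg.duration_s - 0.6
    times = []
    while t < t_end:
        times.append(t)
        rr_ms = cfg.mean_rr_ms
        if a_lf > 0:
            rr_ms += a_lf * math.sin(2 * math.pi * f_lf * t)
        if a_hf > 0:
            rr_ms += a_hf * math.sin(2 * math.pi * f_hf * t)
        if cfg.rr_jitter_ms > 0:
            rr_ms += cfg.rr_jitter_ms * rng.standard_normal()
        t += max(rr_ms, 250.0) / 1000.0  # floor guards against pathological configs
    return np.asarray(times)


def _place_ectopics(
    r: np.ndarray, cfg: EcgSimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Choose ectopic beat indices and apply prematurity + compensatory pause."""
    n = r.size
    labels = np.full(n, "N", dtype="<U1")
    if cfg.ectopic_rate <= 0 or n < 4:
        return r, labels
    eligible = np.arange(2, n - 1)
    if isinstance(cfg.ectopic_pattern, (tuple, list)):
        _, t0, t1 = cfg.ectopic_pattern
        eligible = eligible[(r[eligible] >= t0) & (r[eligible] < t1)]
    pick = eligible[rng.random(eligible.size) < cfg.ectopic_rate]
    # forbid adjacent ectopics so each keeps a normal neighbourhood
    chosen: list[int] = []
    for i in pick:
        if not chosen or i - chosen[-1] > 1:
            chosen.append(int(i))
    r = r.copy()
    for i in chosen:
        rr_prev = r[i] - r[i - 1]
        prem = rng.uniform(0.20, 0.40)
        r[i] = r[i - 1] + (1.0 - prem) * rr_prev  # next beat unchanged => full compensation
        labels[i] = "A"
    return r, labels


def _st_plateau(dt_ms: np.ndarray, offset_uv: float) -> np.ndarray:
    """Smooth ST-level shift covering the [R+60, R+80) ms measurement window."""
    y = np.zeros_like(dt_ms)
    rise = (dt_ms >= 45.0) & (dt_ms < 58.0)
    flat = (dt_ms >= 58.0) & (dt_ms < 165.0)
    fall = (dt_ms >= 165.0) & (dt_ms < 190.0)
    y[rise] = 0.5 * (1 - np.cos(np.pi * (dt_ms[rise] - 45.0) / 13.0))
    y[flat] = 1.0
    y[fall] = 0.5 * (1 + np.cos(np.pi * (dt_ms[fall] - 165.0) / 25.0))
    return offset_uv * y


def generate_ecg(cfg: EcgSimConfig) -> tuple[EcgRecord, GroundTruth]:
    """Simulate one Holter session; deterministic for a fixed ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    r_times = _rr_sequence(cfg, rng)
    if r_times.size < 2:
        raise ConfigurationError("duration_s: too short to hold two beats")
    r_times, labels = _place_ectopics(r_times, cfg, rng)

    st_flags = np.zeros(r_times.size, dtype=bool)
    if cfg.st_fraction > 0 and cfg.st_offset_uV != 0:
        st_flags = rng.random(r_times.size) < cfg.st_fraction

    n_samples = int(round(cfg.duration_s * cfg.fs_hz))
    base = np.zeros(n_samples)
    fs = cfg.fs_hz
    half_w = int(round(0.6 * fs))  # template support: R +/- 600 ms

    for i, (t_r, lab) in enumerate(zip(r_times, labels)):
        c = int(round(t_r * fs))
        lo, hi = max(0, c - half_w), min(n_samples, c + half_w + 1)
        dt_ms = (np.arange(lo, hi) / fs - t_r) * 1000.0
        waves = _ECTOPIC_WAVES if lab == "A" else _NORMAL_WAVES
        seg = np.zeros(hi - lo)
        for amp, mu, sig in waves:
            seg += amp * np.exp(-0.5 * ((dt_ms - mu) / sig) ** 2)
        if st_flags[i] and lab == "N":
            seg += _st_plateau(dt_ms, cfg.st_offset_uV)
        base[lo:hi] += seg

    signals = np.empty((len(cfg.leads), n_samples))
    for j, lead in enumerate(cfg.leads):
        signals[j] = LEAD_SCALE[lead] * base
        if cfg.noise_uV > 0:
            signals[j] += rng.normal(0.0, cfg.noise_uV, n_samples)

    rec = EcgRecord(
        signals=signals,
        fs_hz=fs,
        lead_names=list(cfg.leads),
        start_clock_s=parse_clock(cfg.start_clock),
    )
    q = np.where(labels == "N", r_times + Q_OFFSET_S, np.nan)
    t = np.where(labels == "N", r_times + T_OFFSET_S, np.nan)
    truth = GroundTruth(
        r_times_s=r_times, q_times_s=q, t_times_s=t, labels=labels, st_flags=st_flags
    )
    return rec, truth


@dataclass
class EpSimConfig:
    """Parameters of simulated electroporation pulse delivery.

    Defaults follow the clinical protocol shape: trains of eight 100 µs
    rectangular pulses.  ``droop_frac`` is the fractional linear amplitude
    droop across each pulse; ``noise_frac`` the relative RMS of additive
    noise on V and I.
    """

    n_trains: int = 1
    pulses_per_train: int = 8
    pulse_us: float = 100.0
    amplitude_v: float = 1000.0
    load_ohm: float = 100.0
    waveform_fs_hz: float = 1e7
    pulse_period_us: float = 1000.0
    droop_frac: float = 0.0
    noise_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pulse_us", "amplitude_v", "load_ohm", "waveform_fs_hz",
                     "pulse_period_us", "droop_frac", "noise_frac"):
            setattr(self, name, float(getattr(self, name)))
        self.n_trains = int(self.n_trains)
        self.pulses_per_train = int(self.pulses_per_train)
        self.seed = int(self.seed)

    def validate(self) -> None:
        if self.n_trains < 1:
            raise ConfigurationError("n_trains: must be >= 1")
        if self.pulses_per_train < 1:
            raise ConfigurationError("pulses_per_train: must be >= 1")
        if self.pulse_us <= 0:
            raise ConfigurationError("pulse_us: must be > 0")
        if self.amplitude_v < 0:
            raise ConfigurationError("amplitude_v: must be >= 0")
        if self.load_ohm <= 0:
            raise ConfigurationError("load_ohm: must be > 0")
        if self.waveform_fs_hz < 10.0 / (self.pulse_us * 1e-6):
            raise ConfigurationError(
                "waveform_fs_hz: needs >= 10 samples per pulse width"
            )
        if self.pulse_period_us <= self.pulse_us:
            raise ConfigurationError("pulse_period_us: must exceed pulse_us")
        if not 0.0 <= self.droop_frac < 1.0:
            raise ConfigurationError("droop_frac: must be in [0, 1)")
        if self.noise_frac < 0:
            raise ConfigurationError("noise_frac: must be >= 0")


def generate_ep_waveforms(
    cfg: EpSimConfig, tumor_id: str = "T1", patient_id: str = "P1"
) -> list[PulseTrainRecord]:
    """Emit one V/I record per train; ideal pulses integrate to V^2*tau/R exactly."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.waveform_fs_hz
    tau = cfg.pulse_us * 1e-6
    period = cfg.pulse_period_us * 1e-6
    n_pulse = int(round(tau / dt))  # samples per pulse width; edges inclusive -> n_pulse+1
    n_total = int(round((cfg.pulses_per_train - 1) * period / dt)) + n_pulse + 1 + 2 * n_pulse

    records = []
    for k in range(cfg.n_trains):
        t = np.arange(n_total) * dt
        v = np.zeros(n_total)
        offset = n_pulse  # pre-pulse margin
        for p in range(cfg.pulses_per_train):
            i0 = offset + int(round(p * period / dt))
            u = np.arange(n_pulse + 1) / n_pulse  # 0..1 across the pulse, edges inclusive
            v[i0 : i0 + n_pulse + 1] = cfg.amplitude_v * (1.0 - cfg.droop_frac * u)
        i = v / cfg.load_ohm
        if cfg.noise_frac > 0 and cfg.amplitude_v > 0:
            v = v + rng.normal(0.0, cfg.noise_frac * cfg.amplitude_v, n_total)
            i = i + rng.normal(
                0.0, cfg.noise_frac * cfg.amplitude_v / cfg.load_ohm, n_total
            )
        records.append(
            PulseTrainRecord(
                time_s=t,
                voltage_v=v,
                current_a=i,
                train_id=k,
                tumor_id=tumor_id,
                patient_id=patient_id,
            )
        )
    return records
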