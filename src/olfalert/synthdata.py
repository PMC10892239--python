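"""Synthetic driving-session generator: EEG, brake events, RTs, questionnaires.

Emulates the study protocol the analysis assumes: 30 subjects, two
60-min sessions (one per fragrance condition, ``alerting`` vs
``relaxing``), 19-channel 10-20 montage EEG at 500 Hz, brake events
every 20-40 s (~115-120 trials), fragrance onset at minute 30, and a
condition-dependent effect lasting ~15 min that then decays linearly
over 5 min:

* EEG per channel is a sum of five band-limited oscillatory processes
  (4th-order band-passed Gaussian noise, per-band RMS amplitudes), a
  1/f background, and optional artifacts (frontal biphasic blinks,
  temporal 30-100 Hz muscle bursts).
* In the alerting condition the alpha-band amplitude at frontal
  channels is multiplied by ``1 - alpha_suppression`` from fragrance
  onset for ``effect_duration_min``, relaxing linearly back to 1 over
  ``effect_decay_min``.
* A single shared alpha-band source is added to frontal channels and,
  with a fixed 20-ms lag, to parietal channels, so the imaginary
  cross-spectrum (hence wPLI) is non-zero and condition-sensitive.
* RT(t) = rt_base + drift * t + s(condition) * rt_effect * w(t), with
  s(alerting) = -1, s(relaxing) = +1 and w the same on/decay ramp,
  under multiplicative lognormal noise (strictly positive, right-skewed).
* Optionally, a per-epoch alpha-amplitude fluctuation shared between the
  ``coupling_channels`` signal and the RT mean couples alpha power to RT
  (``rt_alpha_coupling``), emulating the brain-behaviour correlation.

All generators are deterministic given (config, subject, condition):
random streams are derived from ``SimConfig.seed`` with per-purpose
sub-seeds, so the trial-window fast path
(:func:`simulate_trial_epochs`) reproduces the exact brake schedule and
RTs of the full-session path.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EPOCH_LENGTH_S, TRIAL_WINDOW_S, TrialEpoch, bandpass_array
from .spectral import DEFAULT_BANDS, band_by_name

__all__ = [
    "CHANNELS_1020",
    "FRONTAL_CHANNELS",
    "PARIETAL_CHANNELS",
    "CONDITIONS",
    "NoiseModel",
    "SimConfig",
    "Recording",
    "BehavioralRecord",
    "effect_weight",
    "generate_brake_schedule",
    "generate_rt_series",
    "generate_questionnaires",
    "generate_recording",
    "simulate_trial_epochs",
    "write_edf",
    "write_events_csv",
    "config_to_json",
    "config_from_json",
]

#: 19-channel 10-20 montage in recording order.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)
FRONTAL_CHANNELS: tuple[str, ...] = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")
PARIETAL_CHANNELS: tuple[str, ...] = ("P7", "P3", "Pz", "P4", "P8")
TEMPORAL_CHANNELS: tuple[str, ...] = ("T3", "T4")
BLINK_LOADING: dict[str, float] = {"Fp1": 1.0, "Fp2": 1.0, "F7": 0.5, "F8": 0.5}

CONDITIONS: tuple[str, str] = ("alerting", "relaxing")

#: Questionnaire score pairs: (mean_a, sd_a, mean_b, sd_b, lo, hi).
#: Character scores are 1-5 (mean of 3 items), KSS is 1-10.
QUESTIONNAIRE_PARAMS: dict[str, tuple] = {
    # relaxing-character score: (relaxing stimulus, alerting stimulus)
    "relaxing_score": (3.267, 0.646, 2.900, 0.614, 1.0, 5.0),
    # alerting-character score: (alerting stimulus, relaxing stimulus)
    "alerting_score": (3.322, 0.603, 2.944, 0.644, 1.0, 5.0),
    # KSS in the relaxing session: (after, before) -- sleepiness rises
    "kss_relaxing": (6.300, 1.822, 4.967, 2.076, 1.0, 10.0),
    # KSS in the alerting session: no before/after change
    "kss_alerting": (4.967, 1.900, 4.967, 2.076, 1.0, 10.0),
}


@dataclass(frozen=True)
class NoiseModel:
    """Per-band RMS amplitudes (uV), 1/f background scale, artifact rates."""

    band_amplitude_uv: dict[str, float] = field(
        default_factory=lambda: {
            "delta": 8.0, "theta": 6.0, "alpha": 10.0, "beta": 4.0, "gamma": 2.0,
        }
    )
    one_over_f_scale_uv: float = 4.0
    blink_rate_per_min: float = 4.0
    muscle_rate_per_min: float = 1.0
    blink_amplitude_factor: float = 10.0  # x background RMS
    muscle_amplitude_factor: float = 3.0

    def background_rms_uv(self) -> float:
        return float(
            np.sqrt(
                sum(a**2 for a in self.band_amplitude_uv.values())
                + self.one_over_f_scale_uv**2
            )
        )


@dataclass(frozen=True)
class SimConfig:
    """Study-protocol parameters for one simulated cohort."""

    n_subjects: int = 30
    fs_hz: float = 500.0
    channel_labels: tuple[str, ...] = CHANNELS_1020
    session_minutes: float = 60.0
    onset_minute: float = 30.0
    brake_interval_s: tuple[float, float] = (20.0, 40.0)
    alpha_suppression: float = 0.3
    effect_duration_min: float = 15.0
    effect_decay_min: float = 5.0
    rt_base_s: float = 0.7
    rt_drift_s_per_min: float = 0.003
    rt_effect_s: float = 0.05
    rt_noise_sigma: float = 0.15
    rt_alpha_coupling: float = 0.0
    alpha_fluct_sigma: float = 0.2
    coupling_channels: tuple[str, ...] = ("F8",)
    source_gain: float = 0.6
    source_lag_s: float = 0.02
    questionnaire_rho: float = 0.5
    artifacts_enabled: bool = True
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.brake_interval_s
        if not 0 < low <= high:
            raise ValueError(f"brake interval bounds need 0 < low <= high, got {self.brake_interval_s}")
        if not 0 <= self.alpha_suppression < 1:
            raise ValueError(f"alpha_suppression must be in [0, 1), got {self.alpha_suppression}")
        if self.fs_hz <= 2 * 40.0:
            raise ValueError(f"fs_hz must exceed twice the highest band edge (80 Hz), got {self.fs_hz}")
        if len(self.channel_labels) != 19 or len(set(self.channel_labels)) != 19:
            raise ValueError("channel_labels must contain exactly 19 unique montage labels")
        if self.session_minutes <= 0:
            raise ValueError("session_minutes must be positive")
        if self.rt_base_s < 0:
            raise ValueError("rt_base_s must be non-negative")
        if not -1 < self.questionnaire_rho < 1:
            raise ValueError(f"questionnaire_rho must be in (-1, 1), got {self.questionnaire_rho}")

    @property
    def n_epoch_groups(self) -> int:
        return max(1, int(np.ceil(self.session_minutes * 60.0 / EPOCH_LENGTH_S)))


@dataclass
class Recording:
    """Continuous multichannel EEG (uV) with brake-event markers."""

    subject_id: str
    condition: str
    fs_hz: float
    channel_labels: tuple[str, ...]
    samples: np.ndarray  # (n_channels, n_samples)
    brake_times_s: np.ndarray


@dataclass
class BehavioralRecord:
    """Per-session behavioural data: trial RTs and questionnaire scores."""

    subject_id: str
    condition: str
    trial_times_s: np.ndarray
    rt_s: np.ndarray
    kss_before: float = float("nan")
    kss_after: float = float("nan")
    alerting_score: float = float("nan")
    relaxing_score: float = float("nan")


# --- RNG derivation ---------------------------------------------------------

_STREAMS = {"schedule": 1, "rt": 2, "eeg": 3, "artifacts": 4, "fluct": 5,
            "questionnaire": 6, "trial": 7}


def _subject_key(subject_id) -> int:
    return zlib.crc32(str(subject_id).encode())


def _rng(config: SimConfig, subject_id, condition: str | None, stream: str,
         extra: int = 0) -> np.random.Generator:
    cond = 0 if condition is None else CONDITIONS.index(condition) + 1
    return np.random.default_rng(
        [config.seed & 0x7FFFFFFF, _subject_key(subject_id), cond,
         _STREAMS[stream], extra]
    )


def _check_condition(condition: str) -> None:
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


# --- Effect timecourse ------------------------------------------------------


def effect_weight(t_s: np.ndarray, config: SimConfig) -> np.ndarray:
    """Ramp w(t): 1 during the effect window, linear decay to 0, else 0."""
    t = np.asarray(t_s, dtype=float)
    onset = config.onset_minute * 60.0
    plateau_end = onset + config.effect_duration_min * 60.0
    decay_end = plateau_end + config.effect_decay_min * 60.0
    w = np.zeros_like(t)
    w = np.where((t >= onset) & (t < plateau_end), 1.0, w)
    if config.effect_decay_min > 0:
        in_decay = (t >= plateau_end) & (t < decay_end)
        w = np.where(in_decay, 1.0 - (t - plateau_end) / (decay_end - plateau_end), w)
    return w


def _epoch_alpha_fluct(config: SimConfig, subject_id, condition: str) -> np.ndarray:
    """Per-epoch shared log-amplitude fluctuation (zero unless coupling on)."""
    n = config.n_epoch_groups
    if config.rt_alpha_coupling == 0:
        return np.zeros(n)
    rng = _rng(config, subject_id, condition, "fluct")
    return rng.normal(0.0, config.alpha_fluct_sigma, size=n)


# --- Generators -------------------------------------------------------------


def generate_brake_schedule(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Brake-event times with gaps drawn uniformly from the configured range.

    No event falls within the first 10 s (the [-10, 0) s trial window
    must exist) or after the session end.
    """
    low, high = config.brake_interval_s
    session_s = config.session_minutes * 60.0
    times = []
    t = 0.0
    while True:
        t += float(rng.uniform(low, high))
        if t > session_s:
            break
        if t >= TRIAL_WINDOW_S:
            times.append(t)
    return np.asarray(times)


def generate_rt_series(
    config: SimConfig,
    brake_times: np.ndarray,
    condition: str,
    rng: np.random.Generator,
    alpha_fluct: np.ndarray | None = None,
) -> np.ndarray:
    """Per-trial reaction times.

    Deterministic part: base + time-on-task drift + signed condition
    effect scaled by the on/decay ramp w(t) (+ the alpha-coupled shift
    when provided); multiplicative lognormal noise on top.
    """
    _check_condition(condition)
    if config.rt_base_s < 0:
        raise ValueError("rt_base_s must be non-negative")
    brake_times = np.asarray(brake_times, dtype=float)
    if brake_times.size == 0:
        raise ValueError("brake_times is empty")
    sign = -1.0 if condition == "alerting" else 1.0
    det = (
        config.rt_base_s
        + config.rt_drift_s_per_min * brake_times / 60.0
        + sign * config.rt_effect_s * effect_weight(brake_times, config)
    )
    if alpha_fluct is not None and config.rt_alpha_coupling != 0:
        det = det + config.rt_alpha_coupling * config.rt_base_s * np.asarray(alpha_fluct)
    return det * np.exp(rng.normal(0.0, config.rt_noise_sigma, size=brake_times.size))


def generate_questionnaires(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    params: dict[str, tuple] | None = None,
) -> pd.DataFrame:
    """Per-subject questionnaire scores from correlated normal pairs.

    Each score pair (e.g. KSS before/after, or a character score under
    the two stimuli) is drawn with within-subject correlation
    ``questionnaire_rho`` at the configured means/SDs, clipped to its
    scale.  Returns one row per subject.
    """
    if config.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rho = config.questionnaire_rho
    rng = rng if rng is not None else _rng(config, "cohort", None, "questionnaire")
    params = params or QUESTIONNAIRE_PARAMS
    n = config.n_subjects

    def pair(key):
        m1, s1, m2, s2, lo, hi = params[key]
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        a = m1 + s1 * z1
        b = m2 + s2 * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        return np.clip(a, lo, hi), np.clip(b, lo, hi)

    relax_on_relax, relax_on_alert = pair("relaxing_score")
    alert_on_alert, alert_on_relax = pair("alerting_score")
    kss_after_relax, kss_before_relax = pair("kss_relaxing")
    kss_after_alert, kss_before_alert = pair("kss_alerting")
    return pd.DataFrame(
        {
            "subject_id": [f"S{k:02d}" for k in range(n)],
            "relaxing_score_relaxing": relax_on_relax,
            "relaxing_score_alerting": relax_on_alert,
            "alerting_score_alerting": alert_on_alert,
            "alerting_score_relaxing": alert_on_relax,
            "kss_before_relaxing": kss_before_relax,
            "kss_after_relaxing": kss_after_relax,
            "kss_before_alerting": kss_before_alert,
            "kss_after_alerting": kss_after_alert,
        }
    )


# --- EEG synthesis ----------------------------------------------------------


def _band_noise(rng: np.random.Generator, shape: tuple, fs: float,
                low: float, high: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    x = bandpass_array(rng.standard_normal(shape), fs, low, high)
    rms = x.std(axis=-1, keepdims=True)
    return x / np.maximum(rms, 1e-12)


def _pink_noise(rng: np.random.Generator, shape: tuple, fs: float) -> np.ndarray:
    """Unit-RMS 1/f-power background via spectral shaping."""
    white = rng.standard_normal(shape)
    X = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], 1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    x = np.fft.irfft(X * scale, n=shape[-1], axis=-1)
    return x / np.maximum(x.std(axis=-1, keepdims=True), 1e-12)


def _alpha_gain_per_channel(
    config: SimConfig, condition: str, t_s: np.ndarray, fluct: np.ndarray
) -> np.ndarray:
    """(n_channels, n_times) multiplicative alpha-amplitude envelope."""
    labels = config.channel_labels
    t = np.atleast_1d(np.asarray(t_s, dtype=float))
    gain = np.ones((len(labels), t.size))
    if condition == "alerting" and config.alpha_suppression > 0:
        supp = 1.0 - config.alpha_suppression * effect_weight(t, config)
        for ch in FRONTAL_CHANNELS:
            gain[labels.index(ch)] *= supp
    if config.rt_alpha_coupling != 0:
        groups = np.minimum((t // EPOCH_LENGTH_S).astype(int), fluct.size - 1)
        bump = np.exp(fluct[groups])
        for ch in config.coupling_channels:
            gain[labels.index(ch)] *= bump
    return gain


def _synth_eeg(
    config: SimConfig,
    condition: str,
    t_s: np.ndarray,
    rng: np.random.Generator,
    fluct: np.ndarray,
) -> np.ndarray:
    """Oscillatory + 1/f EEG (uV) for the given time axis (artifact-free)."""
    labels = config.channel_labels
    fs = config.fs_hz
    n = t_s.size
    amps = config.noise.band_amplitude_uv
    alpha = band_by_name("alpha")
    x = np.zeros((len(labels), n))
    gain = _alpha_gain_per_channel(config, condition, t_s, fluct)
    for band in DEFAULT_BANDS:
        noise = _band_noise(rng, (len(labels), n), fs, band.low_hz, band.high_hz)
        noise *= amps.get(band.name, 0.0)
        if band.name == "alpha":
            noise *= gain
            # Shared lagged source: frontal at lag 0, parietal delayed.
            src = _band_noise(rng, (1, n), fs, alpha.low_hz, alpha.high_hz)[0]
            src *= amps["alpha"] * config.source_gain
            lag = int(round(config.source_lag_s * fs))
            src_lag = np.roll(src, lag)
            for ch in FRONTAL_CHANNELS:
                idx = labels.index(ch)
                noise[idx] += src * gain[idx]
            for ch in PARIETAL_CHANNELS:
                noise[labels.index(ch)] += src_lag
        x += noise
    x += config.noise.one_over_f_scale_uv * _pink_noise(rng, (len(labels), n), fs)
    return x


def _blink_shape(fs: float, duration_s: float) -> np.ndarray:
    """Biphasic blink transient: slow positive lobe, small fast rebound.

    The asymmetry (75 % of the duration in the positive lobe) keeps the
    spectral energy concentrated below 4 Hz, as eyelid artifacts are.
    """
    n = max(8, int(round(duration_s * fs)))
    split = max(4, int(round(0.75 * n)))
    s = np.zeros(n)
    s[:split] = np.sin(np.pi * np.arange(split) / split) ** 2
    s[split:] = -0.35 * np.sin(np.pi * np.arange(n - split) / max(n - split, 1)) ** 2
    return s


def _add_artifacts(
    x: np.ndarray, config: SimConfig, rng: np.random.Generator,
    duration_s: float | None = None,
) -> None:
    """Add frontal blinks and temporal muscle bursts in place."""
    labels = config.channel_labels
    fs = config.fs_hz
    n = x.shape[1]
    dur = duration_s if duration_s is not None else n / fs
    bg = config.noise.background_rms_uv()

    n_blinks = rng.poisson(config.noise.blink_rate_per_min * dur / 60.0)
    for _ in range(n_blinks):
        width = rng.uniform(0.2, 0.4)
        shape = _blink_shape(fs, width) * config.noise.blink_amplitude_factor * bg
        start = rng.integers(0, max(1, n - shape.size))
        for ch, loading in BLINK_LOADING.items():
            if ch in labels:
                x[labels.index(ch), start : start + shape.size] += loading * shape

    hf_high = min(100.0, 0.45 * fs)
    for ch in TEMPORAL_CHANNELS:
        if ch not in labels:
            continue
        n_bursts = rng.poisson(config.noise.muscle_rate_per_min * dur / 60.0)
        for _ in range(n_bursts):
            width = int(round(rng.uniform(0.5, 2.0) * fs))
            width = min(width, n - 1)
            start = rng.integers(0, max(1, n - width))
            burst = _band_noise(rng, (width,), fs, 30.0, hf_high)
            burst *= np.hanning(width) * config.noise.muscle_amplitude_factor * bg
            x[labels.index(ch), start : start + width] += burst


def generate_recording(
    config: SimConfig, subject_id, condition: str
) -> Recording:
    """Full-session synthetic EEG recording with brake markers.

    Deterministic for a fixed (config, subject, condition).
    """
    _check_condition(condition)
    fs = config.fs_hz
    n = int(round(config.session_minutes * 60.0 * fs))
    t = np.arange(n) / fs
    fluct = _epoch_alpha_fluct(config, subject_id, condition)
    x = _synth_eeg(config, condition, t, _rng(config, subject_id, condition, "eeg"), fluct)
    if config.artifacts_enabled:
        _add_artifacts(x, config, _rng(config, subject_id, condition, "artifacts"))
    brakes = generate_brake_schedule(config, _rng(config, subject_id, condition, "schedule"))
    return Recording(
        subject_id=str(subject_id),
        condition=condition,
        fs_hz=fs,
        channel_labels=tuple(config.channel_labels),
        samples=x,
        brake_times_s=brakes,
    )


def generate_behavioral(
    config: SimConfig, subject_id, condition: str,
    brake_times: np.ndarray | None = None,
) -> BehavioralRecord:
    """RT series for a session; brake schedule regenerated if not given."""
    _check_condition(condition)
    if brake_times is None:
        brake_times = generate_brake_schedule(
            config, _rng(config, subject_id, condition, "schedule")
        )
    fluct = _epoch_alpha_fluct(config, subject_id, condition)
    groups = np.minimum((brake_times // EPOCH_LENGTH_S).astype(int), fluct.size - 1)
    rts = generate_rt_series(
        config, brake_times, condition, _rng(config, subject_id, condition, "rt"),
        alpha_fluct=fluct[groups],
    )
    return BehavioralRecord(
        subject_id=str(subject_id),
        condition=condition,
        trial_times_s=np.asarray(brake_times, dtype=float),
        rt_s=rts,
    )


def simulate_trial_epochs(
    config: SimConfig,
    subject_id,
    condition: str,
    epochs: tuple[int, ...] | None = None,
    trials_per_epoch: int | dict[int, int] | None = None,
) -> tuple[list[TrialEpoch], BehavioralRecord]:
    """Trial-window fast path: synthesize only the 10-s pre-brake windows.

    Uses the same brake schedule, RT draws and per-window signal
    construction as :func:`generate_recording` followed by trial
    extraction, but skips the continuous between-trial signal, so large
    replicate cohorts stay cheap.  ``epochs`` restricts to the listed
    5-min epoch groups and ``trials_per_epoch`` truncates each group
    (reduced trial counts for scaled-down cohorts); an int truncates
    every group, a mapping sets per-group counts (groups it omits keep
    all their trials, e.g. an untruncated baseline epoch).  The alpha
    gain is evaluated at the brake time and held constant within the
    window.
    """
    _check_condition(condition)
    behavioral = generate_behavioral(config, subject_id, condition)
    times = behavioral.trial_times_s
    groups = (times // EPOCH_LENGTH_S).astype(int)
    keep = np.ones(times.size, dtype=bool)
    if epochs is not None:
        keep &= np.isin(groups, list(epochs))
    if trials_per_epoch is not None:
        for g in np.unique(groups[keep]):
            limit = (
                trials_per_epoch.get(int(g))
                if isinstance(trials_per_epoch, dict)
                else trials_per_epoch
            )
            if limit is None:
                continue
            members = np.flatnonzero(keep & (groups == g))
            keep[members[limit:]] = False

    fluct = _epoch_alpha_fluct(config, subject_id, condition)
    fs = config.fs_hz
    n_win = int(round(TRIAL_WINDOW_S * fs))
    trials: list[TrialEpoch] = []
    for idx in np.flatnonzero(keep):
        t_brake = times[idx]
        rng = _rng(config, subject_id, condition, "trial", extra=int(idx))
        gain = _alpha_gain_per_channel(
            config, condition, np.array([t_brake]), fluct
        )[:, 0]
        x = _synth_window(config, condition, gain, n_win, rng)
        trials.append(
            TrialEpoch(
                subject_id=str(subject_id),
                condition=condition,
                trial_index=int(idx),
                brake_time_s=float(t_brake),
                samples=x,
                fs_hz=fs,
                channel_labels=tuple(config.channel_labels),
                epoch_group=int(groups[idx]),
                rt_s=float(behavioral.rt_s[idx]),
            )
        )
    selected = np.flatnonzero(keep)
    behavioral_sel = BehavioralRecord(
        subject_id=behavioral.subject_id,
        condition=condition,
        trial_times_s=times[selected],
        rt_s=behavioral.rt_s[selected],
    )
    return trials, behavioral_sel


def _synth_window(
    config: SimConfig, condition: str, alpha_gain: np.ndarray,
    n: int, rng: np.random.Generator,
) -> np.ndarray:
    """One trial window with a constant per-channel alpha gain."""
    labels = config.channel_labels
    fs = config.fs_hz
    amps = config.noise.band_amplitude_uv
    alpha = band_by_name("alpha")
    x = np.zeros((len(labels), n))
    for band in DEFAULT_BANDS:
        noise = _band_noise(rng, (len(labels), n), fs, band.low_hz, band.high_hz)
        noise *= amps.get(band.name, 0.0)
        if band.name == "alpha":
            noise *= alpha_gain[:, None]
            src = _band_noise(rng, (1, n), fs, alpha.low_hz, alpha.high_hz)[0]
            src *= amps["alpha"] * config.source_gain
            src_lag = np.roll(src, int(round(config.source_lag_s * fs)))
            for ch in FRONTAL_CHANNELS:
                idx = labels.index(ch)
                noise[idx] += src * alpha_gain[idx]
            for ch in PARIETAL_CHANNELS:
                noise[labels.index(ch)] += src_lag
        x += noise
    x += config.noise.one_over_f_scale_uv * _pink_noise(rng, (len(labels), n), fs)
    if config.artifacts_enabled:
        _add_artifacts(x, config, rng, duration_s=n / fs)
    return x


# --- External interfaces ----------------------------------------------------


def write_edf(recording: Recording, path) -> None:
    """Write a 16-bit EDF file (physical units uV, 1-s data records)."""
    fs = recording.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export needs an integer sampling rate")
    spr = int(round(fs))
    x = np.asarray(recording.samples, dtype=float)
    n_ch, n = x.shape
    n_records = n // spr
    x = x[:, : n_records * spr]

    pmax = np.maximum(np.abs(x).max(axis=1), 1e-6)
    pmin = -pmax
    digital = np.round(x / pmax[:, None] * 32767).astype("<i2")

    def f(text, width):
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join(
        [
            f("0", 8),
            f(f"subject {recording.subject_id}", 80),
            f(f"condition {recording.condition}", 80),
            f("01.01.2000", 8),
            f("00.00.00", 8),
            f(256 * (n_ch + 1), 8),
            f("", 44),
            f(n_records, 8),
            f("1", 8),
            f(n_ch, 4),
        ]
    )
    fields = [
        b"".join(f(lbl, 16) for lbl in recording.channel_labels),
        b"".join(f("", 80) for _ in range(n_ch)),
        b"".join(f("uV", 8) for _ in range(n_ch)),
        b"".join(f(f"{pmin[c]:.6g}"[:8], 8) for c in range(n_ch)),
        b"".join(f(f"{pmax[c]:.6g}"[:8], 8) for c in range(n_ch)),
        b"".join(f(-32768, 8) for _ in range(n_ch)),
        b"".join(f(32767, 8) for _ in range(n_ch)),
        b"".join(f("", 80) for _ in range(n_ch)),
        b"".join(f(spr, 8) for _ in range(n_ch)),
        b"".join(f("", 32) for _ in range(n_ch)),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.write(block)
        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def write_events_csv(records, path) -> None:
    """Events CSV with columns subject, condition, time_s, rt_s."""
    rows = []
    for rec in records:
        for t, rt in zip(rec.trial_times_s, rec.rt_s):
            rows.append(
                {"subject": rec.subject_id, "condition": rec.condition,
                 "time_s": t, "rt_s": rt}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def config_to_json(config: SimConfig) -> str:
    return json.dumps(dataclasses.asdict(config), indent=1)


def config_from_json(text: str) -> SimConfig:
    raw = json.loads(text)
    if "noise" in raw and isinstance(raw["noise"], dict):
        raw["noise"] = NoiseModel(**raw["noise"])
    for key in ("channel_labels", "brake_interval_s", "coupling_channels"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SimConfig(**raw)
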