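"""Preprocessing: raw multichannel EEG to cleaned, epoch-grouped trials.

The fixed stage order is: resample (500 -> 250 Hz) -> zero-phase
band-pass ([1, 40] Hz, 4th-order Butterworth per edge) -> extraction of
10-s pre-brake trials ([-10, 0) s relative to each brake event) ->
threshold-based artifact rejection with channel interpolation -> ICA
blink removal -> grouping into non-overlapping 5-min epochs (epoch
index = floor(brake time / 300 s), 12 groups for a 60-min drive).

Artifact rejection flags a trial-channel when its absolute amplitude
exceeds a peak threshold (default 150 uV) or its high-frequency
(30-100 Hz) power exceeds a multiple (default 5x) of the trial-set
median for that channel; up to 3 flagged channels are interpolated from
the mean of the clean channels, otherwise the trial is dropped.  Every
action is logged.

Blink removal runs FastICA with a fixed seed on the concatenated
trials; components whose absolute correlation with the mean frontal
(Fp1 + Fp2) signal exceeds 0.8 and whose spectral power is concentrated
below 4 Hz are zeroed before inverting the mixing back to channels.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import pearsonr

__all__ = [
    "TrialEpoch",
    "EpochGroupSet",
    "bandpass_array",
    "resample",
    "bandpass",
    "extract_trials",
    "reject_artifacts",
    "remove_blinks",
    "group_epochs",
    "preprocess_recording",
    "read_edf",
    "read_events_csv",
    "save_trials",
    "load_trials",
]

TRIAL_WINDOW_S = 10.0
EPOCH_LENGTH_S = 300.0


@dataclass
class TrialEpoch:
    """One 10-s pre-brake trial: samples over [brake - 10 s, brake)."""

    subject_id: str
    condition: str
    trial_index: int
    brake_time_s: float
    samples: np.ndarray  # (n_channels, 10 s * fs)
    fs_hz: float
    channel_labels: tuple[str, ...]
    epoch_group: int
    rt_s: float = float("nan")

    def __post_init__(self) -> None:
        expected = int(round(TRIAL_WINDOW_S * self.fs_hz))
        if self.samples.shape != (len(self.channel_labels), expected):
            raise ValueError(
                f"trial samples shape {self.samples.shape} != "
                f"({len(self.channel_labels)}, {expected})"
            )


@dataclass
class EpochGroupSet:
    """Mapping epoch_group -> surviving trials, with empty-group log."""

    groups: dict[int, list[TrialEpoch]]
    log: list[str] = field(default_factory=list)

    def trial_counts(self) -> dict[int, int]:
        return {g: len(ts) for g, ts in self.groups.items()}


@lru_cache(maxsize=64)
def _butter_sos(order: int, low_hz: float, high_hz: float, fs: float) -> np.ndarray:
    return sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass_array(
    x: np.ndarray, fs: float, low_hz: float, high_hz: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (``order`` poles per edge)."""
    if not 0 < low_hz < high_hz:
        raise ValueError(f"need 0 < low < high, got [{low_hz}, {high_hz}]")
    if high_hz >= fs / 2:
        raise ValueError(f"high edge {high_hz} Hz >= Nyquist ({fs / 2} Hz)")
    sos = _butter_sos(order, float(low_hz), float(high_hz), float(fs))
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def resample(recording, target_fs: float):
    """Polyphase resampling to ``target_fs``; brake times stay in seconds.

    Upsampling is rejected (out of scope for this pipeline).
    """
    if target_fs <= 0 or recording.fs_hz <= 0:
        raise ValueError("sampling rates must be positive")
    if target_fs > recording.fs_hz:
        raise ValueError(
            f"upsampling {recording.fs_hz} -> {target_fs} Hz is not supported"
        )
    if target_fs == recording.fs_hz:
        return replace(recording, samples=recording.samples.copy())
    frac = Fraction(target_fs / recording.fs_hz).limit_denominator(1000)
    out = sps.resample_poly(
        np.asarray(recording.samples, dtype=float), frac.numerator, frac.denominator, axis=-1
    )
    return replace(recording, samples=out, fs_hz=target_fs)


def bandpass(recording, low_hz: float = 1.0, high_hz: float = 40.0):
    """Zero-phase band-pass of a whole recording, default [1, 40] Hz."""
    out = bandpass_array(recording.samples, recording.fs_hz, low_hz, high_hz)
    return replace(recording, samples=out)


def extract_trials(
    recording,
    rts: Sequence[float] | None = None,
    log: list[str] | None = None,
) -> list[TrialEpoch]:
    """One trial per brake event over the window [t - 10 s, t).

    Brake events with an incomplete window (too close to either end of
    the recording) are skipped and logged.  ``rts`` joins per-trial
    reaction times by brake-event index.
    """
    fs = recording.fs_hz
    n = recording.samples.shape[-1]
    win = int(round(TRIAL_WINDOW_S * fs))
    trials: list[TrialEpoch] = []
    for idx, t in enumerate(np.asarray(recording.brake_times_s, dtype=float)):
        i1 = int(round(t * fs))
        i0 = i1 - win
        if i0 < 0 or i1 > n:
            if log is not None:
                log.append(
                    f"subject {recording.subject_id} {recording.condition}: brake at "
                    f"{t:.1f} s skipped (incomplete [-10, 0) s window)"
                )
            continue
        rt = float(rts[idx]) if rts is not None else float("nan")
        trials.append(
            TrialEpoch(
                subject_id=recording.subject_id,
                condition=recording.condition,
                trial_index=idx,
                brake_time_s=float(t),
                samples=np.array(recording.samples[:, i0:i1], dtype=float),
                fs_hz=fs,
                channel_labels=tuple(recording.channel_labels),
                epoch_group=int(t // EPOCH_LENGTH_S),
                rt_s=rt,
            )
        )
    return trials


def reject_artifacts(
    trials: Sequence[TrialEpoch],
    peak_uv: float = 150.0,
    hf_factor: float = 5.0,
    hf_band: tuple[float, float] = (30.0, 100.0),
    max_flagged: int = 3,
    drop_only: bool = False,
) -> tuple[list[TrialEpoch], list[dict]]:
    """Threshold-based rejection of noisy trial-channels.

    A trial-channel is flagged when its peak absolute amplitude exceeds
    ``peak_uv`` or its high-frequency power exceeds ``hf_factor`` times
    the trial-set median for that channel.  With at most ``max_flagged``
    flagged channels the flagged channels are interpolated from the mean
    of the clean channels (unless ``drop_only``); otherwise the trial is
    dropped.  Returns surviving trials and a log of every action.
    """
    if len(trials) == 0:
        raise ValueError("no trials to screen")
    fs = trials[0].fs_hz
    hf_high = min(hf_band[1], 0.45 * fs)
    X = np.stack([t.samples for t in trials])  # (trial, ch, time)
    peaks = np.abs(X).max(axis=-1)
    hf = bandpass_array(X, fs, hf_band[0], hf_high)
    hf_power = hf.var(axis=-1)
    med = np.median(hf_power, axis=0)
    flagged = (peaks > peak_uv) | (hf_power > hf_factor * np.maximum(med, 1e-12))

    kept: list[TrialEpoch] = []
    log: list[dict] = []
    for k, trial in enumerate(trials):
        bad = np.flatnonzero(flagged[k])
        if bad.size == 0:
            kept.append(trial)
            continue
        entry = {
            "subject": trial.subject_id,
            "condition": trial.condition,
            "trial_index": trial.trial_index,
            "channels": [trial.channel_labels[i] for i in bad],
        }
        if bad.size > max_flagged or drop_only:
            entry["action"] = "dropped"
            log.append(entry)
            continue
        good = np.setdiff1d(np.arange(X.shape[1]), bad)
        samples = trial.samples.copy()
        samples[bad] = samples[good].mean(axis=0)
        entry["action"] = "interpolated"
        log.append(entry)
        kept.append(replace(trial, samples=samples))
    return kept, log


def _lowfreq_fraction(source: np.ndarray, fs: float, lf_hz: float) -> float:
    spec = np.abs(np.fft.rfft(source)) ** 2
    freqs = np.fft.rfftfreq(source.size, 1.0 / fs)
    total = spec.sum()
    if total <= 0:
        return 0.0
    return float(spec[freqs < lf_hz].sum() / total)


def remove_blinks(
    trials: Sequence[TrialEpoch],
    seed: int = 0,
    corr_threshold: float = 0.8,
    lf_hz: float = 4.0,
    lf_fraction: float = 0.5,
    min_trials: int = 20,
) -> tuple[list[TrialEpoch], dict]:
    """Zero ICA components matching the blink signature.

    FastICA (fixed seed) decomposes the concatenated trials; a component
    is removed when |corr| with the mean Fp1/Fp2 signal exceeds
    ``corr_threshold`` and more than ``lf_fraction`` of its power lies
    below ``lf_hz``.  On decomposition failure the input is returned
    unchanged with ``info["failed"] = True``.
    """
    from sklearn.decomposition import FastICA

    if len(trials) < min_trials:
        raise ValueError(
            f"ICA needs >= {min_trials} trials for a stable decomposition, "
            f"got {len(trials)}"
        )
    labels = trials[0].channel_labels
    fs = trials[0].fs_hz
    frontal_idx = [labels.index(ch) for ch in ("Fp1", "Fp2") if ch in labels]
    if not frontal_idx:
        raise ValueError("montage lacks Fp1/Fp2; cannot form the blink reference")
    X = np.concatenate([t.samples for t in trials], axis=1)  # (ch, T)
    info: dict = {"n_removed": 0, "removed": [], "failed": False}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica = FastICA(
                n_components=X.shape[0],
                random_state=seed,
                whiten="unit-variance",
                max_iter=1000,
            )
            S = ica.fit_transform(X.T)  # (T, k)
    except Exception as exc:  # decomposition failure: report, pass through
        warnings.warn(f"ICA decomposition failed ({exc}); trials returned unchanged")
        info["failed"] = True
        return list(trials), info

    ref = X[frontal_idx].mean(axis=0)
    removed = []
    for k in range(S.shape[1]):
        comp = S[:, k]
        if comp.std() == 0 or ref.std() == 0:
            continue
        r = abs(pearsonr(comp, ref).statistic)
        if r > corr_threshold and _lowfreq_fraction(comp, fs, lf_hz) > lf_fraction:
            removed.append(k)
    if removed:
        S = S.copy()
        S[:, removed] = 0.0
    X_clean = ica.inverse_transform(S).T
    info["n_removed"] = len(removed)
    info["removed"] = removed

    out: list[TrialEpoch] = []
    n_win = trials[0].samples.shape[1]
    for k, trial in enumerate(trials):
        out.append(replace(trial, samples=X_clean[:, k * n_win : (k + 1) * n_win]))
    return out, info


def group_epochs(
    trials: Sequence[TrialEpoch], session_minutes: float = 60.0
) -> EpochGroupSet:
    """Group trials into non-overlapping 5-min epochs by brake time."""
    n_groups = max(1, math.ceil(session_minutes / 5.0))
    groups: dict[int, list[TrialEpoch]] = {g: [] for g in range(n_groups)}
    for trial in trials:
        groups.setdefault(trial.epoch_group, []).append(trial)
    log = [f"epoch group {g} is empty" for g in range(n_groups) if not groups[g]]
    return EpochGroupSet(groups=groups, log=log)


def preprocess_recording(
    recording,
    rts: Sequence[float] | None = None,
    target_fs: float = 250.0,
    band: tuple[float, float] = (1.0, 40.0),
    ica_seed: int = 0,
    reject_kwargs: dict | None = None,
    blink_kwargs: dict | None = None,
    session_minutes: float = 60.0,
) -> tuple[EpochGroupSet, dict]:
    """Run the full fixed-order chain on one recording."""
    log: dict = {"extract": [], "reject": [], "blinks": {}, "groups": []}
    rec = resample(recording, target_fs)
    rec = bandpass(rec, *band)
    trials = extract_trials(rec, rts=rts, log=log["extract"])
    if trials:
        trials, log["reject"] = reject_artifacts(trials, **(reject_kwargs or {}))
    if len(trials) >= 20:
        trials, log["blinks"] = remove_blinks(
            trials, seed=ica_seed, **(blink_kwargs or {})
        )
    else:
        log["blinks"] = {"skipped": f"only {len(trials)} trials; ICA needs >= 20"}
    grouped = group_epochs(trials, session_minutes=session_minutes)
    log["groups"] = grouped.log
    return grouped, log


# --- External interfaces ---------------------------------------------------


def read_edf(path):
    """Read an EDF recording (channels in uV) via mne.

    Brake events are not stored in the EDF; join them from the events
    CSV written alongside (see :func:`read_events_csv`).
    """
    import mne

    from .synthdata import Recording

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> uV
    return Recording(
        subject_id="",
        condition="",
        fs_hz=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        samples=data,
        brake_times_s=np.array([]),
    )


def read_events_csv(path) -> pd.DataFrame:
    """Events CSV with columns subject, condition, time_s, rt_s."""
    df = pd.read_csv(path)
    required = {"subject", "condition", "time_s", "rt_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events CSV {path} lacks columns {sorted(missing)}")
    return df


def save_trials(trials: Sequence[TrialEpoch], path) -> None:
    """Persist cleaned trials as an .npz array with a JSON sidecar."""
    if not trials:
        raise ValueError("no trials to save")
    X = np.stack([t.samples for t in trials])
    np.savez_compressed(path, samples=X)
    meta = {
        "fs_hz": trials[0].fs_hz,
        "channel_labels": list(trials[0].channel_labels),
        "trials": [
            {
                "subject_id": t.subject_id,
                "condition": t.condition,
                "trial_index": t.trial_index,
                "brake_time_s": t.brake_time_s,
                "epoch_group": t.epoch_group,
                "rt_s": None if np.isnan(t.rt_s) else t.rt_s,
            }
            for t in trials
        ],
    }
    sidecar = str(path)
    sidecar = sidecar[: -len(".npz")] if sidecar.endswith(".npz") else sidecar
    with open(sidecar + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_trials(path) -> list[TrialEpoch]:
    with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as z:
        X = z["samples"]
    sidecar = str(path)
    sidecar = sidecar[: -len(".npz")] if sidecar.endswith(".npz") else sidecar
    with open(sidecar + ".json") as fh:
        meta = json.load(fh)
    out = []
    for k, t in enumerate(meta["trials"]):
        out.append(
            TrialEpoch(
                subject_id=t["subject_id"],
                condition=t["condition"],
                trial_index=t["trial_index"],
                brake_time_s=t["brake_time_s"],
                samples=X[k],
                fs_hz=meta["fs_hz"],
                channel_labels=tuple(meta["channel_labels"]),
                epoch_group=t["epoch_group"],
                rt_s=float("nan") if t["rt_s"] is None else t["rt_s"],
            )
        )
    return out
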