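"""Band power spectral density via the short-time Fourier transform.

A trial is a 10-s multichannel pre-brake EEG segment.  Power is computed
from Hann-tapered STFT segments (default 1-s window, 50 % overlap, i.e.
1 Hz resolution and 19 segments per 10-s trial) and summed over segment
times and in-band frequency bins, yielding one absolute PSD value per
(channel, band):

    PSD(band) = sum_t sum_{f in [f1, f2)} P(t, f)

The one-sided spectrogram is scaled so that summing ``P(t, f)`` over all
frequency bins recovers the energy of the windowed segment (Parseval);
values are therefore in uV^2 * samples and strictly non-negative.

Band edges are half-open ``[low, high)`` so the five canonical EEG bands
partition [1, 40) Hz without double counting shared edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import get_window

__all__ = [
    "Band",
    "DEFAULT_BANDS",
    "band_by_name",
    "stft_complex",
    "stft_spectrogram",
    "band_psd",
    "trial_band_powers",
]


@dataclass(frozen=True)
class Band:
    """A named frequency band with half-open edges ``[low_hz, high_hz)``."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"[{self.low_hz}, {self.high_hz})"
            )


#: Canonical analysis bands: delta, theta, alpha, beta, gamma.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 1.0, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 12.0),
    Band("beta", 12.0, 30.0),
    Band("gamma", 30.0, 40.0),
)


def band_by_name(name: str, bands: Sequence[Band] = DEFAULT_BANDS) -> Band:
    for band in bands:
        if band.name == name:
            return band
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in bands]}")


def _segmentation(n_samples: int, fs: float, window_s: float, overlap: float):
    nperseg = int(round(window_s * fs))
    if nperseg < 2:
        raise ValueError(f"window of {window_s} s too short at fs={fs}")
    if nperseg > n_samples:
        raise ValueError(
            f"window ({nperseg} samples) longer than signal ({n_samples})"
        )
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    step = max(1, int(round(nperseg * (1.0 - overlap))))
    starts = np.arange(0, n_samples - nperseg + 1, step)
    return nperseg, step, starts


def stft_complex(
    x: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered complex STFT.

    Parameters
    ----------
    x
        Signal array, shape ``(..., n_samples)``.
    fs
        Sampling rate in Hz.
    window_s, overlap
        Segment length in seconds and fractional overlap.

    Returns
    -------
    freqs : (n_freqs,) one-sided frequency axis in Hz.
    X : complex array, shape ``(..., n_segments, n_freqs)``.
    """
    x = np.asarray(x, dtype=float)
    nperseg, _, starts = _segmentation(x.shape[-1], fs, window_s, overlap)
    win = get_window("hann", nperseg, fftbins=True)
    idx = starts[:, None] + np.arange(nperseg)[None, :]
    segments = x[..., idx] * win
    X = np.fft.rfft(segments, axis=-1)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return freqs, X


def stft_spectrogram(
    x: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-sided STFT power, Parseval-scaled.

    Returns ``(freqs, times, P)`` where ``P`` has shape
    ``(..., n_segments, n_freqs)`` and ``P[..., t, :].sum()`` equals the
    energy of the Hann-windowed segment ``t``.  ``times`` are segment
    centres in seconds.
    """
    x = np.asarray(x, dtype=float)
    nperseg, _, starts = _segmentation(x.shape[-1], fs, window_s, overlap)
    freqs, X = stft_complex(x, fs, window_s=window_s, overlap=overlap)
    # One-sided doubling: interior bins carry the conjugate half's power.
    scale = np.full(freqs.shape, 2.0)
    scale[0] = 1.0
    if nperseg % 2 == 0:
        scale[-1] = 1.0
    P = (np.abs(X) ** 2) * (scale / nperseg)
    times = (starts + nperseg / 2.0) / fs
    return freqs, times, P


def band_psd(freqs: np.ndarray, P: np.ndarray, band: Band) -> np.ndarray:
    """Sum spectrogram power over segments and in-band bins ``[low, high)``.

    ``P`` has shape ``(..., n_segments, n_freqs)``; the result drops the
    last two axes.  Raises if the band contains no frequency bins.
    """
    freqs = np.asarray(freqs)
    in_band = (freqs >= band.low_hz) & (freqs < band.high_hz)
    if not in_band.any():
        df = freqs[1] - freqs[0] if len(freqs) > 1 else float("nan")
        raise ValueError(
            f"band {band.name!r} [{band.low_hz}, {band.high_hz}) Hz contains "
            f"no bins at frequency resolution {df} Hz"
        )
    return P[..., in_band].sum(axis=(-2, -1))


def trial_band_powers(
    samples: np.ndarray,
    fs: float,
    bands: Iterable[Band] = DEFAULT_BANDS,
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> dict[str, np.ndarray]:
    """Per-channel band PSD for one trial.

    ``samples`` is ``(n_channels, n_samples)``; returns a mapping
    ``band name -> (n_channels,)`` array of PSD values.
    """
    freqs, _, P = stft_spectrogram(samples, fs, window_s=window_s, overlap=overlap)
    return {band.name: band_psd(freqs, P, band) for band in bands}
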