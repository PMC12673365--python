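"""Shared STFT configuration.

One fixed analysis setup (4096-sample Hann window, 1024 hop) is used by the
spectral manipulations and every feature extractor, and is recorded in
output metadata so feature values are comparable across runs.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

__all__ = ["STFT_N_FFT", "STFT_HOP", "stft_transform", "stft", "istft", "bin_frequencies"]

STFT_N_FFT = 4096
STFT_HOP = 1024

_CACHE: dict[float, ShortTimeFFT] = {}


def stft_transform(fs: float) -> ShortTimeFFT:
    if fs not in _CACHE:
        _CACHE[fs] = ShortTimeFFT(hann(STFT_N_FFT, sym=False), hop=STFT_HOP, fs=fs, mfft=STFT_N_FFT)
    return _CACHE[fs]


def stft(x: np.ndarray, fs: float) -> np.ndarray:
    """Complex STFT, shape (n_bins, n_frames)."""
    x = np.asarray(x, dtype=float)
    if x.size < STFT_N_FFT:
        raise ValueError(f"signal shorter than one {STFT_N_FFT}-sample analysis window")
    return stft_transform(fs).stft(x)


def istft(S: np.ndarray, fs: float, n_samples: int) -> np.ndarray:
    """Inverse STFT truncated/padded to n_samples."""
    y = stft_transform(fs).istft(S, k1=n_samples)
    return np.asarray(y[:n_samples], dtype=float)


def bin_frequencies(fs: float) -> np.ndarray:
    return np.fft.rfftfreq(STFT_N_FFT, d=1.0 / fs)
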