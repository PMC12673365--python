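"""The three audio descriptors the analysis rests on, plus HPSS and hpr.

* spectral centroid — magnitude-weighted mean frequency, the classic
  brightness correlate;
* harmonicity strength — presence of fifth/minor-third/major-third relations
  in the spectrum, measured by projecting a 12-bin chroma vector onto the
  tone-network (Tonnetz) basis; its absolute scale is arbitrary and only
  correlations consume it;
* percussive loudness — BS.1770 integrated loudness of the percussive
  component after harmonic-percussive source separation (HPSS).

HPSS follows the median-filtering scheme: on the magnitude spectrogram a
median across time enhances sustained (harmonic) structure and a median
across frequency enhances transient/noisy (percussive) structure; soft
Wiener-like masks resynthesize the two components. The harmonic-to-percussive
energy ratio (hpr) of those components summarises how tonal a stimulus is —
high for sustained tones, low for noisy or transient material.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .bs1770 import LOUDNESS_FLOOR, integrated_loudness
from .dsp import bin_frequencies, istft, stft
from .stimuli import Audio

__all__ = [
    "AudioFeatures",
    "spectral_centroid",
    "hpss",
    "percussive_loudness",
    "harmonicity_strength",
    "harmonic_percussive_ratio",
    "mean_spectrum",
    "extract_features",
]

#: Median-filter kernel length (frames for harmonic, bins for percussive).
HPSS_KERNEL = 31
#: Soft-mask exponent (2 = Wiener-like power masks).
HPSS_POWER = 2.0
#: Bins below this frequency are excluded from chroma (DC / rumble guard).
CHROMA_FMIN = 60.0


@dataclass(frozen=True)
class AudioFeatures:
    """Feature vector for one stimulus."""

    spectral_centroid: float  # Hz
    harmonicity_strength: float  # dimensionless, [0, 1]
    percussive_loudness: float  # LUFS
    hpr: float  # harmonic/percussive energy ratio
    percussive_at_floor: bool = False  # percussive part below the gating floor


def _magnitude(a: Audio) -> np.ndarray:
    if not np.any(a.samples):
        raise ValueError("silent input")
    return np.abs(stft(a.samples, a.sample_rate))


#: Relative magnitude floor for the centroid (−60 dB of the spectrogram
#: peak): keeps window-sidelobe leakage spread over thousands of empty bins
#: from biasing the weighted mean upward.
CENTROID_FLOOR = 1e-3


def spectral_centroid(a: Audio) -> float:
    """Magnitude-weighted mean frequency, frames pooled by their energy."""
    mag = _magnitude(a)
    mag = np.where(mag >= CENTROID_FLOOR * mag.max(), mag, 0.0)
    freqs = bin_frequencies(a.sample_rate)
    total = mag.sum()
    if total == 0.0:
        raise ValueError("silent input")
    return float((freqs[:, None] * mag).sum() / total)


def hpss(a: Audio) -> tuple[Audio, Audio]:
    """Median-filtering harmonic-percussive separation with soft masks.

    Returns (harmonic, percussive); under the power-2 masks the two
    components sum to the input in the STFT domain.
    """
    S = stft(a.samples, a.sample_rate)
    mag = np.abs(S)
    harm = median_filter(mag, size=(1, HPSS_KERNEL), mode="reflect")
    perc = median_filter(mag, size=(HPSS_KERNEL, 1), mode="reflect")
    hp = harm**HPSS_POWER
    pp = perc**HPSS_POWER
    denom = hp + pp
    denom[denom == 0.0] = 1.0
    mask_h = hp / denom
    y_h = istft(S * mask_h, a.sample_rate, a.samples.size)
    y_p = istft(S * (1.0 - mask_h), a.sample_rate, a.samples.size)
    return (
        Audio(y_h, a.sample_rate, a.label, provenance=a.provenance + "|harmonic"),
        Audio(y_p, a.sample_rate, a.label, provenance=a.provenance + "|percussive"),
    )


def percussive_loudness(a: Audio, *, _components: tuple[Audio, Audio] | None = None) -> tuple[float, bool]:
    """BS.1770 integrated loudness of the percussive HPSS component.

    Returns (lufs, at_floor); a nearly pure sustained tone leaves almost no
    percussive energy and reports the gating floor with the flag set.
    """
    if not np.any(a.samples):
        raise ValueError("silent input")
    _, perc = _components if _components is not None else hpss(a)
    lufs = integrated_loudness(perc.samples, perc.sample_rate)
    return lufs, lufs <= LOUDNESS_FLOOR


# Tone-network pitch classes relative to the root: unison/octaves, the
# fifths chain (fifth, fifth-of-fifth), the major third, and the minor third
# above the fifth — exactly the classes the first ten partials occupy.
_TONE_NETWORK_PCS = (0, 7, 2, 4, 10)


def _chroma(a: Audio) -> np.ndarray:
    """Energy chroma (12 pitch classes, C = 0), L1-normalized.

    Computed from the full-length windowed periodogram rather than the STFT:
    a pitch-class band is only ~±3 % wide in frequency, so at STFT resolution
    the mainlobe of a strong partial leaks into the neighboring class; the
    full-length transform makes bin-to-class assignment essentially exact.
    """
    if not np.any(a.samples):
        raise ValueError("silent input")
    x = a.samples * np.hanning(a.samples.size)
    energy = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(a.samples.size, d=1.0 / a.sample_rate)
    keep = freqs >= CHROMA_FMIN
    midi = 69.0 + 12.0 * np.log2(freqs[keep] / 440.0)
    pc = np.mod(np.round(midi).astype(int), 12)
    chroma = np.bincount(pc, weights=energy[keep], minlength=12)[:12]
    total = chroma.sum()
    if total == 0.0:
        raise ValueError("silent input")
    return chroma / total


def harmonicity_strength(a: Audio, root_hz: float = 261.63) -> float:
    """Excess chroma mass on the root's tone-network pitch classes, in [0, 1].

    The tone network spans the root, its fifth and stacked fifth, its major
    third, and the minor third above the fifth — the fifth/third relations a
    harmonic series projects into chroma space. The statistic is the chroma
    mass on those classes in excess of the flat-chroma baseline, rescaled so
    flat (noisy) chroma scores ~0 and chroma fully concentrated on the
    network scores 1. Removing tonal mass from a network class can only
    lower it, so partial reduction with noise retained drives it down. Its
    absolute scale is arbitrary; only correlations consume it.
    """
    chroma = _chroma(a)
    root_pc = int(np.round(69.0 + 12.0 * np.log2(root_hz / 440.0))) % 12
    template = [(root_pc + pc) % 12 for pc in _TONE_NETWORK_PCS]
    mass = float(chroma[template].sum())
    baseline = len(template) / 12.0
    return max(0.0, (mass - baseline) / (1.0 - baseline))


def harmonic_percussive_ratio(a: Audio, *, _components: tuple[Audio, Audio] | None = None) -> float:
    """energy(harmonic) / energy(percussive) from HPSS; inf if no percussive."""
    harm, perc = _components if _components is not None else hpss(a)
    e_p = float(np.sum(perc.samples**2))
    e_h = float(np.sum(harm.samples**2))
    if e_p == 0.0:
        return float("inf")
    return e_h / e_p


def mean_spectrum(a: Audio, floor_db: float = -120.0) -> tuple[np.ndarray, np.ndarray]:
    """(frequencies, time-averaged magnitude spectrum in dB) for report plots."""
    mag = _magnitude(a)
    mean_mag = mag.mean(axis=1)
    ref = mean_mag.max() or 1.0
    db = 20.0 * np.log10(np.maximum(mean_mag / ref, 10.0 ** (floor_db / 20.0)))
    return bin_frequencies(a.sample_rate), db


def extract_features(a: Audio) -> AudioFeatures:
    """All descriptors for one stimulus (HPSS computed once)."""
    components = hpss(a)
    lufs, at_floor = percussive_loudness(a, _components=components)
    return AudioFeatures(
        spectral_centroid=spectral_centroid(a),
        harmonicity_strength=harmonicity_strength(a),
        percussive_loudness=lufs,
        hpr=harmonic_percussive_ratio(a, _components=components),
        percussive_at_floor=at_floor,
    )
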