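"""Synthesis and manipulation of the instrument-like stimuli.

The stimulus set mirrors the study design: five loudness-matched
harmonic-plus-noise tones at C4 (261.63 Hz, 2 s, 44.1 kHz) standing in for
sampled flute, oboe, French horn, violin and piano, plus the two
manipulations applied to them:

* partial reduction — the lowest 1..10 partials are removed with narrow
  STFT-domain notches while blowing/bowing/striking noise between the
  partials is retained;
* morphing — stage-wise timbral interpolation between two tones at target
  fractions 0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0, realised as linear
  magnitude-spectrogram interpolation with phase taken from the
  dominant-weight source, followed by re-loudness-matching.

The five presets differ chiefly in their harmonic-to-noise balance: horn and
oboe are almost purely tonal, flute carries strong blowing noise, piano a
strong striking transient, and the violin keeps strong partials above the
10th on top of bowing noise. That balance is what drives the harmonic/
percussive statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.io import wavfile

from .bs1770 import LOUDNESS_FLOOR, integrated_loudness
from .dsp import istft, stft

__all__ = [
    "C4_HZ",
    "TARGET_LUFS",
    "MORPH_RATIOS",
    "NoiseProfile",
    "ToneSpec",
    "Audio",
    "PRESETS",
    "synth_tone",
    "remove_partials",
    "morph",
    "loudness_match",
    "write_wav",
    "read_wav",
    "partial_reduction_series",
    "morph_series",
]

C4_HZ = 261.63
TARGET_LUFS = -23.0
#: The seven morph stages, as fraction of the target timbre.
MORPH_RATIOS = (0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0)

#: Notch half-width for partial removal (±3 bins of a 4096-pt analysis at
#: 44.1 kHz, i.e. ≈ ±32 Hz around each partial).
NOTCH_HALFWIDTH_HZ = 32.3


@dataclass(frozen=True)
class NoiseProfile:
    """Stationary noise plus attack transient, relative to unit partial sum.

    level: broadband noise amplitude; tilt_db_per_octave: spectral tilt of
    that noise (0 = white); attack_level: amplitude of the short broadband
    onset burst; attack_decay_ms: its exponential decay constant.
    """

    level: float = 0.0
    tilt_db_per_octave: float = 0.0
    attack_level: float = 0.0
    attack_decay_ms: float = 30.0


@dataclass(frozen=True)
class ToneSpec:
    label: str
    partial_amps: tuple[float, ...]
    noise: NoiseProfile = field(default_factory=NoiseProfile)
    f0: float = C4_HZ
    duration: float = 2.0
    sample_rate: float = 44100.0

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        amps = np.asarray(self.partial_amps, dtype=float)
        if amps.size < 1 or not np.all(np.isfinite(amps)) or np.any(amps < 0):
            raise ValueError("partial amplitudes must be finite and nonnegative")
        if amps.size * self.f0 >= self.sample_rate / 2:
            raise ValueError("highest partial at or above Nyquist")


@dataclass(frozen=True)
class Audio:
    """Rendered mono waveform plus a record of how it was produced."""

    samples: np.ndarray
    sample_rate: float
    label: str
    provenance: str = "original"

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


def _decaying_amps(n: int, p: float) -> tuple[float, ...]:
    k = np.arange(1, n + 1, dtype=float)
    return tuple(k**-p)


# Preset contrast: harmonic-to-noise balance. Horn/oboe nearly pure tone;
# flute strong steady blowing noise + steep partial decay; piano strong
# striking transient + fairly steep decay; violin slow decay (strong
# partials above the 10th) over audible bowing noise.
PRESETS: dict[str, ToneSpec] = {
    "flute": ToneSpec(
        "flute",
        _decaying_amps(16, 1.5),
        NoiseProfile(level=0.045, tilt_db_per_octave=-3.0, attack_level=0.02, attack_decay_ms=20.0),
    ),
    "oboe": ToneSpec(
        "oboe",
        _decaying_amps(18, 0.8),
        NoiseProfile(level=0.004, tilt_db_per_octave=-3.0, attack_level=0.01, attack_decay_ms=15.0),
    ),
    "horn": ToneSpec(
        "horn",
        _decaying_amps(16, 1.2),
        NoiseProfile(level=0.003, tilt_db_per_octave=-4.0, attack_level=0.01, attack_decay_ms=25.0),
    ),
    "violin": ToneSpec(
        "violin",
        _decaying_amps(24, 0.6),
        NoiseProfile(level=0.020, tilt_db_per_octave=-3.0, attack_level=0.02, attack_decay_ms=15.0),
    ),
    "piano": ToneSpec(
        "piano",
        _decaying_amps(16, 1.7),
        NoiseProfile(level=0.026, tilt_db_per_octave=-2.0, attack_level=0.24, attack_decay_ms=150.0),
    ),
}


def _shaped_noise(rng: np.random.Generator, n: int, fs: float, tilt_db_per_octave: float) -> np.ndarray:
    """Unit-RMS Gaussian noise with the given spectral tilt (ref 500 Hz)."""
    white = rng.standard_normal(n)
    if tilt_db_per_octave == 0.0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f = np.maximum(f, 50.0)  # keep the tilt from blowing up at DC
    gain = (f / 500.0) ** (tilt_db_per_octave / (20.0 * np.log10(2.0)))
    shaped = np.fft.irfft(spec * gain, n=n)
    return shaped / np.sqrt(np.mean(shaped**2))


def synth_tone(spec: ToneSpec, seed: int = 0) -> Audio:
    """Render a harmonic-plus-noise tone; bit-identical for equal spec+seed."""
    fs, n = spec.sample_rate, int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)

    amps = np.asarray(spec.partial_amps, dtype=float)
    harmonic = np.zeros(n)
    for k, a in enumerate(amps, start=1):
        if a > 0.0:
            harmonic += a * np.sin(2.0 * np.pi * k * spec.f0 * t)
    scale = np.sum(amps) or 1.0
    harmonic /= scale

    x = harmonic
    if spec.noise.level > 0.0:
        x = x + spec.noise.level * _shaped_noise(rng, n, fs, spec.noise.tilt_db_per_octave)
    if spec.noise.attack_level > 0.0:
        tau = spec.noise.attack_decay_ms / 1000.0
        x = x + spec.noise.attack_level * rng.standard_normal(n) * np.exp(-t / tau)

    # onset/offset ramps against clicks; long enough that their spectral
    # splatter stays within each partial's own pitch-class band
    ramp = int(0.060 * fs)
    env = np.ones(n)
    env[:ramp] = 0.5 - 0.5 * np.cos(np.pi * np.arange(ramp) / ramp)
    env[-ramp:] = env[:ramp][::-1]
    x = x * env

    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.5 * x / peak
    return Audio(x, fs, spec.label, provenance="original")


def remove_partials(a: Audio, k: int, f0: float = C4_HZ) -> Audio:
    """Notch out partials 1..k while keeping the noise floor between them.

    Narrow zero notches (± NOTCH_HALFWIDTH_HZ ≈ ±32 Hz) are applied around
    each multiple m·f0, m ≤ k — emulating a spectral editor that removes a
    partial but not the blowing/bowing/striking noise in the surrounding
    frequency range. The notches are brick-wall filters on the full-signal
    spectrum, so a steady partial is suppressed completely rather than down
    to the analysis-window sidelobe floor.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k * f0 >= a.sample_rate / 2:
        raise ValueError("partial above Nyquist")
    spec = np.fft.rfft(a.samples)
    freqs = np.fft.rfftfreq(a.samples.size, d=1.0 / a.sample_rate)
    for m in range(1, k + 1):
        spec[np.abs(freqs - m * f0) <= NOTCH_HALFWIDTH_HZ] = 0.0
    y = np.fft.irfft(spec, n=a.samples.size)
    return Audio(y, a.sample_rate, a.label, provenance=f"partials_removed k={k}")


def morph(a: Audio, b: Audio, ratio: float) -> Audio:
    """Timbral interpolation: |S| = (1−ratio)·|Sa| + ratio·|Sb|.

    Phase is taken from the dominant-weight source (a for ratio ≤ 0.5), so
    the endpoints reconstruct the inputs up to STFT round-trip error.
    """
    if a.sample_rate != b.sample_rate:
        raise ValueError("sample rates differ")
    if a.samples.size != b.samples.size:
        raise ValueError("lengths differ")
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must be in [0, 1]")
    Sa = stft(a.samples, a.sample_rate)
    Sb = stft(b.samples, b.sample_rate)
    mag = (1.0 - ratio) * np.abs(Sa) + ratio * np.abs(Sb)
    phase_src = Sa if ratio <= 0.5 else Sb
    phase = np.angle(phase_src)
    y = istft(mag * np.exp(1j * phase), a.sample_rate, a.samples.size)
    label = f"{a.label}>{b.label}"
    return Audio(y, a.sample_rate, label, provenance=f"morph({a.label},{b.label},{ratio:g})")


def loudness_match(
    audios: Sequence[Audio], target_lufs: float = TARGET_LUFS, tol_lu: float = 0.05, max_iter: int = 4
) -> list[Audio]:
    """Gain every signal to the target BS.1770 integrated loudness.

    Gain-only (no dynamics processing); the gated measure makes the gain
    solution mildly nonlinear, hence the short fixed-point iteration.
    """
    if not audios:
        raise ValueError("empty stimulus set")
    out = []
    for a in audios:
        x = a.samples.astype(float)
        loud = integrated_loudness(x, a.sample_rate)
        if loud <= LOUDNESS_FLOOR:
            raise ValueError(f"stimulus {a.label!r} is silent; cannot loudness-match")
        for _ in range(max_iter):
            if abs(loud - target_lufs) <= tol_lu:
                break
            x = x * 10.0 ** ((target_lufs - loud) / 20.0)
            loud = integrated_loudness(x, a.sample_rate)
        if np.max(np.abs(x)) > 1.0:
            raise ValueError(f"target {target_lufs} LUFS would clip stimulus {a.label!r}")
        out.append(replace(a, samples=x))
    return out


def write_wav(path, a: Audio) -> None:
    """16-bit PCM mono WAV."""
    pcm = np.clip(a.samples, -1.0, 1.0)
    wavfile.write(path, int(a.sample_rate), (pcm * 32767.0).astype(np.int16))


def read_wav(path, label: str | None = None) -> Audio:
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("mono WAV expected")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return Audio(np.asarray(data, dtype=float), float(fs), label or str(path))


def partial_reduction_series(
    spec: ToneSpec, k_max: int = 10, seed: int = 0, target_lufs: float = TARGET_LUFS
) -> list[Audio]:
    """Original (k=0) plus k=1..k_max reduced variants, each loudness-matched.

    Re-matching after the manipulation mirrors the study stimuli: removing
    tonal energy then restoring loudness is what pushes the noise share up.
    """
    base = loudness_match([synth_tone(spec, seed=seed)], target_lufs)[0]
    series = [base]
    for k in range(1, k_max + 1):
        series.extend(loudness_match([remove_partials(base, k, spec.f0)], target_lufs))
    return series


def morph_series(
    a: Audio, b: Audio, ratios: Iterable[float] = MORPH_RATIOS, target_lufs: float = TARGET_LUFS
) -> list[Audio]:
    """Loudness-matched morphs of a→b at the given target fractions."""
    return [loudness_match([morph(a, b, r)], target_lufs)[0] for r in ratios]
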