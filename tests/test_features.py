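"""Audio descriptors: centroid, HPSS, percussive loudness, harmonicity, hpr."""

import numpy as np
import pytest

from timbrecolor.features import (
    extract_features,
    harmonic_percussive_ratio,
    harmonicity_strength,
    hpss,
    mean_spectrum,
    percussive_loudness,
    spectral_centroid,
)
from timbrecolor.stimuli import Audio, NoiseProfile, ToneSpec, synth_tone

FS = 44100.0


def _sine(freq, amp=0.5, seconds=2.0):
    t = np.arange(int(FS * seconds)) / FS
    return Audio(amp * np.sin(2 * np.pi * freq * t), FS, f"sine{freq:g}")


def _click(pos_s=1.0, seconds=2.0, amp=0.9):
    x = np.zeros(int(FS * seconds))
    x[int(pos_s * FS)] = amp
    return Audio(x, FS, "click")


def _noise(seed=0, amp=0.1, seconds=2.0):
    rng = np.random.default_rng(seed)
    return Audio(amp * rng.standard_normal(int(FS * seconds)), FS, "noise")


class TestSpectralCentroid:
    def test_pure_sine(self):
        assert spectral_centroid(_sine(440.0)) == pytest.approx(440.0, abs=5.0)

    def test_equal_partials_average(self):
        t = np.arange(int(FS * 2)) / FS
        x = 0.4 * np.sin(2 * np.pi * 262 * t) + 0.4 * np.sin(2 * np.pi * 524 * t)
        assert spectral_centroid(Audio(x, FS, "two")) == pytest.approx(393.0, abs=8.0)

    def test_silence_rejected(self):
        with pytest.raises(ValueError, match="silent"):
            spectral_centroid(Audio(np.zeros(int(FS * 2)), FS, "zeros"))

    def test_gain_invariant(self):
        a = _sine(500.0)
        scaled = Audio(0.1 * a.samples, FS, "scaled")
        assert spectral_centroid(scaled) == pytest.approx(spectral_centroid(a), rel=1e-9)


class TestHPSS:
    def test_steady_sine_is_harmonic(self):
        harm, perc = hpss(_sine(440.0))
        e_h, e_p = np.sum(harm.samples**2), np.sum(perc.samples**2)
        assert e_h / (e_h + e_p) > 0.9

    def test_click_is_percussive(self):
        harm, perc = hpss(_click())
        e_h, e_p = np.sum(harm.samples**2), np.sum(perc.samples**2)
        assert e_p / (e_h + e_p) > 0.9

    def test_mixture_components_recovered_within_3db(self):
        tone = _sine(440.0, amp=0.3)
        t = np.arange(int(FS * 2)) / FS
        clicks = np.zeros_like(t)
        clicks[:: int(0.25 * FS)] = 0.8  # click train
        mix = Audio(tone.samples + clicks, FS, "mix")
        harm, perc = hpss(mix)
        for est, true in ((harm.samples, tone.samples), (perc.samples, clicks)):
            ratio_db = 10 * np.log10(np.sum(est**2) / np.sum(true**2))
            assert abs(ratio_db) < 3.0

    def test_energy_approximately_conserved(self):
        a = synth_tone(ToneSpec("t", (1.0, 0.5, 0.3), NoiseProfile(level=0.05)), seed=1)
        harm, perc = hpss(a)
        total = (np.sum(harm.samples**2) + np.sum(perc.samples**2)) / np.sum(a.samples**2)
        assert 0.9 <= total <= 1.1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="window"):
            hpss(Audio(np.ones(1024), FS, "short"))


class TestPercussiveLoudness:
    def test_steady_sine_at_floor(self):
        lufs, at_floor = percussive_loudness(_sine(440.0, amp=0.05))
        assert at_floor or lufs < -45.0

    def test_gain_equivariance(self):
        a = _noise(seed=3, amp=0.05)
        l1, _ = percussive_loudness(a)
        l2, _ = percussive_loudness(Audio(2.0 * a.samples, FS, "x2"))
        assert l2 - l1 == pytest.approx(6.0206, abs=0.1)

    def test_piano_preset_more_percussive_than_flute(self, preset_features):
        assert (
            preset_features["piano"][0].percussive_loudness
            > preset_features["flute"][0].percussive_loudness
        )


class TestHarmonicity:
    def test_white_noise_near_baseline(self):
        assert harmonicity_strength(_noise(seed=0)) < 0.1

    def test_harmonic_tone_above_noise(self):
        tone = synth_tone(ToneSpec("t", tuple((1 / k) for k in range(1, 11))), seed=0)
        assert harmonicity_strength(tone) > harmonicity_strength(_noise(seed=0)) + 0.3

    def test_bounded(self):
        tone = synth_tone(ToneSpec("t", (1.0,)), seed=0)
        assert 0.0 <= harmonicity_strength(tone) <= 1.0

    def test_gain_invariant(self):
        tone = synth_tone(ToneSpec("t", tuple((1 / k) for k in range(1, 8))), seed=0)
        half = Audio(0.5 * tone.samples, FS, "half")
        assert harmonicity_strength(half) == pytest.approx(harmonicity_strength(tone), rel=1e-9)


class TestHpr:
    def test_steady_sine_much_greater_than_one(self):
        assert harmonic_percussive_ratio(_sine(440.0)) > 10.0

    def test_click_train_in_noise_below_one(self):
        t = np.arange(int(FS * 2)) / FS
        clicks = np.zeros_like(t)
        clicks[:: int(0.2 * FS)] = 0.9
        mix = Audio(clicks + 0.02 * np.random.default_rng(1).standard_normal(t.size), FS, "cl")
        assert harmonic_percussive_ratio(mix) < 1.0

    def test_hpr_anticorrelates_with_percussive_loudness(self, preset_features):
        """Across the 55 reduction stimuli the tonal share falls exactly as
        the percussive share rises; the study reports the same strong
        negative association on its stimuli."""
        hprs, pls = [], []
        for feats in preset_features.values():
            hprs += [np.log10(f.hpr) for f in feats]
            pls += [f.percussive_loudness for f in feats]
        r = np.corrcoef(hprs, pls)[0, 1]
        assert r < -0.7


class TestMeanSpectrum:
    def test_sine_has_single_dominant_bin(self):
        freqs, db = mean_spectrum(_sine(1000.0))
        peak = freqs[np.argmax(db)]
        assert peak == pytest.approx(1000.0, abs=11.0)
        assert np.sum(db > -20.0) < 10  # narrow peak

    def test_notches_visible_after_reduction(self, preset_series):
        freqs, db0 = mean_spectrum(preset_series["oboe"][0])
        _, db10 = mean_spectrum(preset_series["oboe"][10])
        f0 = 261.63
        for m in range(1, 6):
            band = np.abs(freqs - m * f0) < 10.0
            assert db10[band].max() < db0[band].max() - 40.0

    def test_sustained_presets_keep_high_hpr_after_reduction(self, preset_features):
        """The tonal instruments stay pitch-dominant (hpr > 10) after removing
        ten partials; the noisy/transient ones drop below 3."""
        for name in ("horn", "oboe", "violin"):
            assert preset_features[name][10].hpr > 10.0
        for name in ("flute", "piano"):
            assert preset_features[name][10].hpr < 3.0


class TestExtractFeatures:
    def test_bundle_consistent_with_parts(self):
        a = synth_tone(ToneSpec("t", (1.0, 0.4, 0.2), NoiseProfile(level=0.02)), seed=2)
        f = extract_features(a)
        assert f.spectral_centroid == pytest.approx(spectral_centroid(a), rel=1e-12)
        assert f.harmonicity_strength == pytest.approx(harmonicity_strength(a), rel=1e-12)
        assert f.hpr > 1.0
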