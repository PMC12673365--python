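"""Report charts: mean spectra, morph color-distance curves, score bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .features import harmonic_percussive_ratio, mean_spectrum

__all__ = ["plot_mean_spectra", "plot_morph_trend", "plot_scores"]


def plot_mean_spectra(audios, labels=None, fmax=8000.0, ax=None):
    """Overlaid time-averaged spectra with each signal's hpr in the legend."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    labels = labels or [a.label for a in audios]
    for a, label in zip(audios, labels):
        freqs, db = mean_spectrum(a)
        keep = freqs <= fmax
        ax.plot(freqs[keep], db[keep], lw=0.8, label=f"{label} (hpr {harmonic_percussive_ratio(a):.1f})")
    ax.set_xlabel("frequency [Hz]")
    ax.set_ylabel("mean magnitude [dB]")
    ax.legend(fontsize=8)
    return ax


def plot_morph_trend(trend, ax=None):
    """Scatter of per-subject ΔE points plus the stage-mean curve and trend line."""
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(trend.points["stage"], trend.points["de"], s=8, alpha=0.4)
    ax.plot(trend.curve.index, trend.curve.values, "o-", color="k", label="stage mean")
    xs = np.array([0, 6])
    coeffs = np.polyfit(trend.points["stage"], trend.points["de"], 1)
    ax.plot(xs, np.polyval(coeffs, xs), "--", color="r", label=f"trend (slope {trend.slope_overall:.2f})")
    ax.set_xlabel("morph stage (0 = original, 6 = target)")
    ax.set_ylabel("ΔE to original-tone response")
    ax.set_title(trend.pair)
    ax.legend(fontsize=8)
    return ax


def plot_scores(scores, ax=None):
    """Per-subject mean ΔE bars with the grade-band edges marked."""
    from .scoring import GRADE_EDGES

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.5))
    ids = [s.subject_id for s in scores]
    means = [s.mean_de for s in scores]
    ax.bar(ids, means, color=["tab:blue" if s.is_synesthete else "tab:gray" for s in scores])
    for edge in GRADE_EDGES:
        ax.axhline(edge, ls=":", lw=0.8, color="k")
    ax.set_ylabel("mean ΔE")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    return ax
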