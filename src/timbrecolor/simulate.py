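"""Synthetic response cohorts with the statistical structure the analysis assumes.

The study's human data are not redistributable, so tests and examples run on
simulated subjects. A subject is a :class:`SubjectProfile`: a stable
instrument→color anchor map (synesthetic "photisms"), per-feature color
slopes that tilt the response as the stimulus' audio features move away from
the original instrument's baseline (emulating the observed lightness-with-
brightness and blue-with-percussiveness patterns), and response noise.

Consistency control differs by grade:

* synesthete-grade profiles (excellent / very well / satisfactory) re-see
  nearly the same color on a repeat: the second presentation is displaced
  from the first by a CIEDE2000 magnitude drawn tightly around the profile's
  target mean ΔE (lognormal, 10 % spread, random direction). A per-subject
  mean over five instruments then lands reliably inside the intended grade
  band — a purely isotropic Gaussian jitter cannot do that, because the ΔE
  between two independently jittered copies has a coefficient of variation
  of ~0.42, far wider than the 3-ΔE grade bands.
* "poor" (non-synesthete) profiles pick weakly consistent colors: isotropic
  Gaussian jitter in Lab around the anchor, with sigma calibrated by Monte
  Carlo so the expected repeat ΔE matches the target (well above the 16 ΔE
  synesthesia limit).

Everything is deterministic given the seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colorspace import ColorLab, ColorRGB, delta_e_ciede2000, lab_to_srgb, rgb_to_hex, rgb_to_hsl
from .features import extract_features
from .scoring import Grade
from .stimuli import MORPH_RATIOS, PRESETS, morph_series, partial_reduction_series

__all__ = [
    "SubjectProfile",
    "DEFAULT_ANCHORS",
    "DEFAULT_SYN_COEFFS",
    "GRADE_TARGET_DE",
    "calibrate_jitter",
    "make_cohort",
    "simulate_responses",
    "build_manifest",
    "stimulus_features",
]

#: Anchor colors per instrument (Lab, comfortably inside the sRGB gamut).
DEFAULT_ANCHORS: dict[str, ColorLab] = {
    "flute": ColorLab(72.0, 2.0, 42.0),  # pale yellow
    "violin": ColorLab(46.0, 48.0, 30.0),  # deep red
    "horn": ColorLab(55.0, -38.0, 32.0),  # green
    "piano": ColorLab(42.0, 12.0, -42.0),  # blue
    "oboe": ColorLab(60.0, 30.0, 48.0),  # orange
}

#: Planted feature→Lab slopes for synesthetes: lightness rises with the
#: spectral centroid; b* falls (bluer) as percussive loudness rises.
DEFAULT_SYN_COEFFS: dict[str, tuple[float, float, float]] = {
    "spectral_centroid": (0.003, 0.0, 0.0),  # L per Hz
    "percussive_loudness": (0.0, 0.0, -0.8),  # b per LU
    "harmonicity_strength": (0.0, 0.0, 0.0),
}

#: Target mean repeat-ΔE per grade band (band interior, not an edge).
GRADE_TARGET_DE: dict[Grade, float] = {
    Grade.EXCELLENT: 6.0,
    Grade.VERY_WELL: 11.5,
    Grade.SATISFACTORY: 14.5,
    Grade.POOR: 32.0,
}

#: Lognormal spread of the controlled repeat displacement.
CONSISTENCY_SPREAD = 0.10


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    anchors: dict[str, ColorLab]
    coeffs: dict[str, tuple[float, float, float]]
    jitter_sigma: float  # Lab response noise (non-repeat variation)
    target_grade: Grade
    target_mean_de: float

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "anchors": {k: [v.L, v.a, v.b] for k, v in self.anchors.items()},
            "coeffs": {k: list(v) for k, v in self.coeffs.items()},
            "jitter_sigma": self.jitter_sigma,
            "target_grade": self.target_grade.value,
            "target_mean_de": self.target_mean_de,
        }


def _clamp_lab(lab: np.ndarray) -> ColorLab:
    return ColorLab(float(np.clip(lab[0], 0.0, 100.0)), float(lab[1]), float(lab[2]))


def _quantize(lab: ColorLab) -> tuple[ColorRGB, ColorLab]:
    """Project to the 8-bit sRGB gamut (what a picker delivers) and back."""
    rgb = lab_to_srgb(lab, clamp=True)
    from .colorspace import srgb_to_lab

    return rgb, srgb_to_lab(rgb)


def calibrate_jitter(
    target_mean_de: float,
    n_mc: int = 2000,
    seed: int = 0,
    anchors: dict[str, ColorLab] | None = None,
    tol: float = 0.05,
) -> float:
    """Monte-Carlo calibration: sigma such that E[ΔE between two jittered,
    gamut-clamped copies of an anchor] ≈ target within ``tol`` (relative)."""
    if target_mean_de < 0:
        raise ValueError("target mean ΔE must be nonnegative")
    if target_mean_de == 0.0:
        return 0.0
    anchor_list = list((anchors or DEFAULT_ANCHORS).values())
    rng = np.random.default_rng(seed)

    def expected_de(sigma: float) -> float:
        des = []
        for i in range(n_mc):
            base = anchor_list[i % len(anchor_list)]
            a = np.array([base.L, base.a, base.b])
            _, l1 = _quantize(_clamp_lab(a + sigma * rng.standard_normal(3)))
            _, l2 = _quantize(_clamp_lab(a + sigma * rng.standard_normal(3)))
            des.append(delta_e_ciede2000(l1, l2))
        return float(np.mean(des))

    lo, hi = 0.0, 5.0
    while expected_de(hi) < target_mean_de:
        hi *= 2.0
        if hi > 200.0:
            raise ValueError(f"target ΔE {target_mean_de} unreachable within the sRGB gamut")
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        e = expected_de(mid)
        if abs(e - target_mean_de) <= tol * target_mean_de:
            return mid
        if e < target_mean_de:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_cohort(
    seed: int = 0,
    n_excellent: int = 2,
    n_very_well: int = 4,
    n_satisfactory: int = 4,
    n_poor: int = 10,
    poor_sigma: float | None = None,
) -> list[SubjectProfile]:
    """The default 20-subject cohort mirroring the study's grade census.

    ``poor_sigma`` overrides the Monte-Carlo calibration of the
    non-synesthete jitter (useful to avoid re-calibrating in replicates).
    """
    if poor_sigma is None:
        poor_sigma = calibrate_jitter(GRADE_TARGET_DE[Grade.POOR], seed=seed)
    profiles = []
    counts = (
        (Grade.EXCELLENT, n_excellent),
        (Grade.VERY_WELL, n_very_well),
        (Grade.SATISFACTORY, n_satisfactory),
        (Grade.POOR, n_poor),
    )
    idx = itertools.count(1)
    for grade, n in counts:
        for _ in range(n):
            i = next(idx)
            if grade is Grade.POOR:
                coeffs = {k: (0.0, 0.0, 0.0) for k in DEFAULT_SYN_COEFFS}
                sigma = poor_sigma
            else:
                coeffs = dict(DEFAULT_SYN_COEFFS)
                sigma = 2.0  # small non-repeat response noise
            profiles.append(
                SubjectProfile(
                    subject_id=f"s{i:03d}",
                    anchors=dict(DEFAULT_ANCHORS),
                    coeffs=coeffs,
                    jitter_sigma=sigma,
                    target_grade=grade,
                    target_mean_de=GRADE_TARGET_DE[grade],
                )
            )
    return profiles


def build_manifest(
    instruments=tuple(PRESETS),
    k_max: int = 10,
    morph_pairs=(),
) -> pd.DataFrame:
    """Stimulus manifest: one row per stimulus (originals listed once).

    Columns: stimulus_id, kind ∈ {original, reduced, morph}, series
    (instrument name, or "src>tgt" for morphs), level (0 for originals,
    k for reduced, ordinal stage 1..5 for morphs).
    """
    rows = [
        {"stimulus_id": f"{inst}_orig", "kind": "original", "series": inst, "level": 0}
        for inst in instruments
    ]
    for inst in instruments:
        rows += [
            {"stimulus_id": f"{inst}_tt{k}", "kind": "reduced", "series": inst, "level": k}
            for k in range(1, k_max + 1)
        ]
    inner = [r for r in MORPH_RATIOS if 0.0 < r < 1.0]
    for src, tgt in morph_pairs:
        rows += [
            {
                "stimulus_id": f"{src}>{tgt}_m{int(round(100 * r))}",
                "kind": "morph",
                "series": f"{src}>{tgt}",
                "level": stage,
            }
            for stage, r in enumerate(inner, start=1)
        ]
    return pd.DataFrame(rows)


def stimulus_features(
    manifest: pd.DataFrame, seed: int = 0, k_max: int = 10
) -> pd.DataFrame:
    """Synthesize every manifest stimulus and extract its features.

    Returns a frame indexed like the manifest with feature columns plus the
    morph ratio where applicable. This is the expensive step; do it once and
    reuse across simulated replicates.
    """
    instruments = manifest.loc[manifest["kind"] == "original", "series"].tolist()
    audio = {}
    for inst in instruments:
        series = partial_reduction_series(PRESETS[inst], k_max=k_max, seed=seed)
        audio[f"{inst}_orig"] = series[0]
        for k in range(1, k_max + 1):
            audio[f"{inst}_tt{k}"] = series[k]
    inner = [r for r in MORPH_RATIOS if 0.0 < r < 1.0]
    for pair in manifest.loc[manifest["kind"] == "morph", "series"].unique():
        src, tgt = pair.split(">")
        morphs = morph_series(audio[f"{src}_orig"], audio[f"{tgt}_orig"], ratios=inner)
        for r, m in zip(inner, morphs):
            audio[f"{src}>{tgt}_m{int(round(100 * r))}"] = m
    recs = []
    for row in manifest.itertuples():
        f = extract_features(audio[row.stimulus_id])
        recs.append(
            {
                "stimulus_id": row.stimulus_id,
                "spectral_centroid": f.spectral_centroid,
                "harmonicity_strength": f.harmonicity_strength,
                "percussive_loudness": f.percussive_loudness,
                "hpr": f.hpr,
            }
        )
    return pd.DataFrame(recs)


def _controlled_displacement(
    rng: np.random.Generator, start: ColorLab, target_de: float, max_tries: int = 25
) -> ColorLab:
    """A Lab color at CIEDE2000 distance ≈ target_de from start, in gamut."""
    from scipy.optimize import brentq

    for _ in range(max_tries):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        s_hi = 4.0
        start_vec = np.array([start.L, start.a, start.b])

        def f(s: float) -> float:
            return delta_e_ciede2000(start, _clamp_lab(start_vec + s * u)) - target_de

        while f(s_hi) < 0 and s_hi < 500.0:
            s_hi *= 2.0
        if f(s_hi) < 0:
            continue
        s = brentq(f, 0.0, s_hi, xtol=1e-3)
        candidate = _clamp_lab(start_vec + s * u)
        _, realized = _quantize(candidate)
        if abs(delta_e_ciede2000(start, realized) - target_de) <= max(0.05 * target_de, 0.3):
            return realized
    raise ValueError(f"could not realize ΔE {target_de:.1f} from {start} within the gamut")


def _base_color(profile: SubjectProfile, row, features: pd.DataFrame) -> np.ndarray:
    """Anchor (or morph-interpolated anchor) plus feature modulation, as Lab vector."""
    feat = features.loc[row.stimulus_id]
    if row.kind == "morph":
        src, tgt = row.series.split(">")
        inner = [r for r in MORPH_RATIOS if 0.0 < r < 1.0]
        ratio = inner[int(row.level) - 1]
        a_s, a_t = profile.anchors[src], profile.anchors[tgt]
        base = (1.0 - ratio) * np.array([a_s.L, a_s.a, a_s.b]) + ratio * np.array(
            [a_t.L, a_t.a, a_t.b]
        )
        baseline = features.loc[f"{src}_orig"]
    else:
        a = profile.anchors[row.series]
        base = np.array([a.L, a.a, a.b])
        baseline = features.loc[f"{row.series}_orig"]
    for feat_name, slope in profile.coeffs.items():
        base = base + np.asarray(slope) * (feat[feat_name] - baseline[feat_name])
    return base


def simulate_responses(
    profiles: list[SubjectProfile],
    manifest: pd.DataFrame,
    features: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a response table (one row per subject × stimulus × presentation).

    Original stimuli get two presentations; everything else one. Colors are
    delivered as 8-bit sRGB with hex and HSL columns, like a picker would.
    """
    features = features.set_index("stimulus_id") if "stimulus_id" in features.columns else features
    rng = np.random.default_rng(seed)
    rows = []

    def emit(profile, stimulus_id, presentation, rgb: ColorRGB):
        hsl = rgb_to_hsl(rgb)
        rows.append(
            {
                "subject_id": profile.subject_id,
                "stimulus_id": stimulus_id,
                "presentation": presentation,
                "r": rgb.r,
                "g": rgb.g,
                "b": rgb.b,
                "hex": rgb_to_hex(rgb),
                "h": hsl.h,
                "s": hsl.s,
                "l": hsl.l,
                "missing": False,
            }
        )

    for profile in profiles:
        controlled = profile.target_grade is not Grade.POOR
        for row in manifest.itertuples():
            base = _base_color(profile, row, features)
            first = _clamp_lab(base + profile.jitter_sigma * rng.standard_normal(3))
            rgb1, lab1 = _quantize(first)
            emit(profile, row.stimulus_id, 1, rgb1)
            if row.kind != "original":
                continue
            if controlled:
                d = profile.target_mean_de * float(
                    np.exp(CONSISTENCY_SPREAD * rng.standard_normal())
                )
                lab2 = _controlled_displacement(rng, lab1, d)
                rgb2 = lab_to_srgb(lab2, clamp=True)
            else:
                second = _clamp_lab(base + profile.jitter_sigma * rng.standard_normal(3))
                rgb2, _ = _quantize(second)
            emit(profile, row.stimulus_id, 2, rgb2)
    return pd.DataFrame(rows)


def ground_truth_json(profiles: list[SubjectProfile]) -> str:
    """Planted profiles (anchors, slopes, grades) for downstream checking."""
    return json.dumps([p.to_dict() for p in profiles], indent=2)
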