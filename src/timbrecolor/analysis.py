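"""Correlation and morph-trend statistics over response tables.

Two families of statistics:

* correlations between manipulation level (number of removed partials, morph
  stage) or extracted audio features and the group-mean color channels
  (saturation, lightness, red, green, blue — hue is refused because it is a
  circular variable);
* morph color-distance trends: CIEDE2000 distance from each morph-stage
  response to the two repeat responses for the originating timbre, with an
  ordinary-least-squares trend line over the ordinal stage axis, fitted
  either over all seven stages ("overall", both repeats of each endpoint
  entering as separate points) or over the five genuinely morphed stages
  ("morphed only").

Correlations are computed on group-mean colors per stimulus level (one point
per level), the reading consistent with the published p-values; a pooled
per-subject mode is available via ``per_subject=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .colorspace import ColorRGB, delta_e_ciede2000, srgb_to_lab

__all__ = [
    "CorrelationResult",
    "MorphTrend",
    "correlate",
    "channel_series",
    "feature_correlations",
    "morph_distance_curves",
    "trend_stats",
    "group_trend_table",
]

#: Channels the correlation analysis accepts (column name in a response table).
CHANNELS = {"S": "s", "L": "l", "R": "r", "G": "g", "B": "b"}

MORPH_STAGES = 7  # ordinal stages 0..6: original, 5 morph ratios, target


@dataclass(frozen=True)
class CorrelationResult:
    predictor: str
    channel: str
    r: float
    p: float
    n: int
    stars: str
    alpha_corrected: float
    significant: bool
    instrument: str | None = None
    group: str | None = None


@dataclass(frozen=True)
class MorphTrend:
    """Color-distance trend for one directed morph pair within one group."""

    source: str
    target: str
    points: pd.DataFrame = field(repr=False)  # columns: subject_id, ref, stage, de
    curve: pd.Series = field(repr=False)  # mean ΔE per stage
    slope_overall: float = float("nan")
    range_overall: float = float("nan")
    slope_morphed_only: float = float("nan")
    range_morphed_only: float = float("nan")

    @property
    def pair(self) -> str:
        return f"{self.source}>{self.target}"


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def correlate(
    xs,
    ys,
    bonferroni_n: int | None = None,
    *,
    predictor: str = "x",
    channel: str = "y",
    instrument: str | None = None,
    group: str | None = None,
) -> CorrelationResult:
    """Pearson r with a two-sided t-test p-value.

    Stars follow the uncorrected 0.05/0.01/0.001 thresholds as printed in
    report tables; the ``significant`` flag uses the Bonferroni-corrected
    alpha when ``bonferroni_n`` is given.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.size < 3:
        raise ValueError("need two equal-length series with n >= 3")
    if not (np.all(np.isfinite(xs)) and np.all(np.isfinite(ys))):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
        raise ValueError("zero-variance series: correlation undefined")
    res = stats.pearsonr(xs, ys)
    alpha = 0.05 / bonferroni_n if bonferroni_n else 0.05
    return CorrelationResult(
        predictor,
        channel,
        float(res.statistic),
        float(res.pvalue),
        xs.size,
        _stars(float(res.pvalue)),
        alpha,
        bool(res.pvalue < alpha),
        instrument,
        group,
    )


def _subject_mask(responses: pd.DataFrame, subjects) -> pd.DataFrame:
    if subjects is None:
        return responses
    return responses[responses["subject_id"].isin(list(subjects))]


def channel_series(
    responses: pd.DataFrame,
    manifest: pd.DataFrame,
    channel: str,
    instrument: str | None = None,
    subjects=None,
    kind: str = "reduced",
) -> pd.DataFrame:
    """Group-mean channel value per manipulation level.

    Levels: 0 = original (both presentations pooled), then k = 1..10 removed
    partials (``kind="reduced"``) or morph stages (``kind="morph"``, with
    ``instrument`` naming the directed pair "src>tgt"). Hue is refused: it is
    circular (0° ≡ 360°), so a linear correlation on it is meaningless.
    """
    if channel.upper() == "H":
        raise ValueError("hue is circular; linear correlation on it is refused")
    if channel.upper() not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {sorted(CHANNELS)}")
    col = CHANNELS[channel.upper()]
    sel = manifest[manifest["kind"].isin([kind, "original"])]
    if instrument is not None:
        sel = sel[sel["series"] == instrument]
    rows = _subject_mask(responses, subjects).merge(
        sel[["stimulus_id", "level"]], on="stimulus_id"
    )
    if rows.empty:
        raise ValueError("no responses match the requested series")
    out = rows.groupby("level")[col].mean().reset_index().rename(columns={col: "value"})
    return out.sort_values("level").reset_index(drop=True)


def feature_correlations(
    responses: pd.DataFrame,
    manifest: pd.DataFrame,
    features: pd.DataFrame,
    subjects=None,
    channels=("S", "L", "R", "G", "B"),
    feature_names=("spectral_centroid", "harmonicity_strength", "percussive_loudness"),
    instruments=None,
    bonferroni_n: int | None = None,
    group: str | None = None,
    kind: str = "reduced",
) -> pd.DataFrame:
    """Channel-vs-feature Pearson table (one row per channel × feature).

    With ``instruments`` given, each instrument's reduction series is
    analyzed separately (level-mean colors vs the feature at each level,
    n = levels). With ``instruments=None`` all stimuli of the requested kind
    are pooled (the morph-study reading, Bonferroni n = 15 by default there).
    """
    features = features.set_index("stimulus_id") if "stimulus_id" in features.columns else features
    recs = []
    series_list = instruments if instruments is not None else [None]
    for inst in series_list:
        sel = manifest[manifest["kind"].isin([kind, "original"])]
        if inst is not None:
            sel = sel[sel["series"] == inst]
        rows = _subject_mask(responses, subjects).merge(
            sel[["stimulus_id", "level"]], on="stimulus_id"
        )
        means = rows.groupby("stimulus_id")[[CHANNELS[c.upper()] for c in channels]].mean()
        for channel in channels:
            for feat in feature_names:
                xs = features.loc[means.index, feat].to_numpy(dtype=float)
                ys = means[CHANNELS[channel.upper()]].to_numpy(dtype=float)
                recs.append(
                    correlate(
                        xs,
                        ys,
                        bonferroni_n,
                        predictor=feat,
                        channel=channel,
                        instrument=inst,
                        group=group,
                    )
                )
    return pd.DataFrame([r.__dict__ for r in recs])


def _lab_of(row) -> object:
    return srgb_to_lab(ColorRGB(int(row.r), int(row.g), int(row.b)))


def morph_distance_curves(
    responses: pd.DataFrame,
    manifest: pd.DataFrame,
    source: str,
    target: str,
    subjects=None,
) -> MorphTrend:
    """ΔE-to-origin curves for one directed morph pair.

    For every subject, each of the two repeat responses to the source
    original acts as a reference color; the ΔE from that reference to the
    response at every ordinal stage (0 = source original, 1..5 = morphs,
    6 = target original) yields two curves per subject. Endpoint stages
    contribute both repeat responses as separate points.
    """
    pair = f"{source}>{target}"
    responses = _subject_mask(responses, subjects)
    morph_rows = manifest[(manifest["kind"] == "morph") & (manifest["series"] == pair)]
    stage_stimuli: dict[int, list[str]] = {
        0: [f"{source}_orig"],
        6: [f"{target}_orig"],
        **{int(r.level): [r.stimulus_id] for r in morph_rows.itertuples()},
    }
    records = []
    for subject_id, sub in responses.groupby("subject_id"):
        sub = sub[~sub["missing"].astype(bool)]
        refs = sub[sub["stimulus_id"] == f"{source}_orig"].sort_values("presentation")
        if len(refs) < 2:
            continue  # partial curve: no complete reference pair
        ref_labs = [_lab_of(r) for r in refs.itertuples()]
        for stage, stimuli in sorted(stage_stimuli.items()):
            stage_rows = sub[sub["stimulus_id"].isin(stimuli)]
            for row in stage_rows.itertuples():
                lab = _lab_of(row)
                for ref_idx, ref in enumerate(ref_labs, start=1):
                    records.append(
                        {
                            "subject_id": subject_id,
                            "ref": ref_idx,
                            "stage": stage,
                            "de": delta_e_ciede2000(ref, lab),
                        }
                    )
    points = pd.DataFrame(records, columns=["subject_id", "ref", "stage", "de"])
    if points.empty:
        raise ValueError(f"no usable responses for morph pair {pair}")
    curve = points.groupby("stage")["de"].mean()
    s_all, r_all = trend_stats(points, "overall")
    s_m, r_m = trend_stats(points, "morphed_only")
    return MorphTrend(source, target, points, curve, s_all, r_all, s_m, r_m)


def trend_stats(points: pd.DataFrame, mode: str = "overall") -> tuple[float, float]:
    """(slope, range) of the ΔE trend over ordinal stages.

    slope: OLS coefficient of ΔE on the stage index over the included points
    (overall: stages 0..6; morphed_only: stages 1..5). range: max − min of
    the per-stage mean ΔE over the included stages.
    """
    if mode not in ("overall", "morphed_only"):
        raise ValueError(f"unknown mode {mode!r}")
    sel = points if mode == "overall" else points[(points["stage"] >= 1) & (points["stage"] <= 5)]
    stages = sel["stage"].to_numpy(dtype=float)
    des = sel["de"].to_numpy(dtype=float)
    if np.unique(stages).size < 2:
        raise ValueError("need at least two stages for a trend")
    slope = float(np.polyfit(stages, des, 1)[0])
    stage_means = sel.groupby("stage")["de"].mean()
    return slope, float(stage_means.max() - stage_means.min())


def group_trend_table(
    responses: pd.DataFrame,
    manifest: pd.DataFrame,
    groups: dict[str, list[str]],
    pairs=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(slopes, ranges) tables: one row per directed pair + a Mean row,
    columns ``{group}_overall`` and ``{group}_morphed`` per group."""
    if pairs is None:
        pairs = sorted(
            manifest.loc[manifest["kind"] == "morph", "series"].unique()
        )
    slope_rows, range_rows = {}, {}
    for pair in pairs:
        source, target = pair.split(">")
        srow, rrow = {}, {}
        for gname, members in groups.items():
            trend = morph_distance_curves(responses, manifest, source, target, members)
            srow[f"{gname}_overall"] = trend.slope_overall
            srow[f"{gname}_morphed"] = trend.slope_morphed_only
            rrow[f"{gname}_overall"] = trend.range_overall
            rrow[f"{gname}_morphed"] = trend.range_morphed_only
        slope_rows[pair] = srow
        range_rows[pair] = rrow
    slopes = pd.DataFrame.from_dict(slope_rows, orient="index")
    ranges = pd.DataFrame.from_dict(range_rows, orient="index")
    slopes.loc["Mean"] = slopes.mean()
    ranges.loc["Mean"] = ranges.mean()
    return slopes, ranges
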