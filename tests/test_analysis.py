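"""Correlation and morph-trend statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from timbrecolor.analysis import (
    channel_series,
    correlate,
    feature_correlations,
    group_trend_table,
    morph_distance_curves,
    trend_stats,
)
from timbrecolor.reference import trend_range_table, trend_slope_table
from timbrecolor.scoring import load_responses


def _brute_force_pearson(xs, ys):
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    xm, ym = xs - xs.mean(), ys - ys.mean()
    r = np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2))
    n = xs.size
    t = r * np.sqrt((n - 2) / (1 - r**2))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), n - 2)
    return r, p


class TestCorrelate:
    def test_perfect_linear(self):
        xs = np.arange(10.0)
        res = correlate(xs, 2 * xs)
        assert res.r == pytest.approx(1.0)
        assert res.stars == "***"

    def test_independent_permutation_near_zero(self):
        rng = np.random.default_rng(0)
        xs = rng.normal(size=500)
        ys = rng.permutation(xs)
        assert abs(correlate(xs, ys).r) < 0.1

    def test_matches_closed_form_on_toy_set(self):
        xs = [1.0, 2.0, 4.0, 4.5, 6.0, 7.0, 8.5, 9.0, 11.0, 12.5, 13.0, 15.0]
        ys = [2.1, 1.9, 4.2, 3.8, 6.6, 6.1, 8.3, 9.5, 10.0, 13.0, 12.0, 14.2]
        res = correlate(xs, ys)
        r, p = _brute_force_pearson(xs, ys)
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_bonferroni_controls_significance_flag(self):
        xs = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        ys = [1.1, 2.3, 2.8, 4.2, 4.8, 6.3]
        plain = correlate(xs, ys)
        strict = correlate(xs, ys, bonferroni_n=1000)
        assert plain.significant and not strict.significant
        assert plain.stars == strict.stars  # stars stay uncorrected

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [1.0, 2.0])


def _toy_responses_and_manifest():
    rows = []
    manifest = [{"stimulus_id": "fl_orig", "kind": "original", "series": "fl", "level": 0}]
    for k in range(1, 4):
        manifest.append({"stimulus_id": f"fl_tt{k}", "kind": "reduced", "series": "fl", "level": k})
    # two subjects; lightness l rises with level for A, constant for B
    for subj, lvals in (("A", [0.2, 0.3, 0.4, 0.5]), ("B", [0.6, 0.6, 0.6, 0.6])):
        for k, l in enumerate(lvals):
            stim = "fl_orig" if k == 0 else f"fl_tt{k}"
            pres = (1, 2) if k == 0 else (1,)
            for p in pres:
                rows.append(
                    {
                        "subject_id": subj,
                        "stimulus_id": stim,
                        "presentation": p,
                        "r": 100,
                        "g": 100,
                        "b": 100,
                        "h": 0.0,
                        "s": 0.0,
                        "l": l,
                        "missing": False,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(manifest)


class TestChannelSeries:
    def test_hand_computed_group_means(self):
        responses, manifest = _toy_responses_and_manifest()
        series = channel_series(responses, manifest, "L", instrument="fl")
        # level 0 pools both presentations of both subjects: (0.2+0.2+0.6+0.6)/4
        assert series["value"].tolist() == pytest.approx([0.4, 0.45, 0.5, 0.55])
        assert series["level"].tolist() == [0, 1, 2, 3]

    def test_constant_color_gives_constant_series(self):
        responses, manifest = _toy_responses_and_manifest()
        series = channel_series(responses, manifest, "R", instrument="fl")
        assert np.ptp(series["value"].to_numpy()) == 0.0

    def test_hue_refused_as_circular(self):
        responses, manifest = _toy_responses_and_manifest()
        with pytest.raises(ValueError, match="circular"):
            channel_series(responses, manifest, "H", instrument="fl")

    def test_unknown_channel_rejected(self):
        responses, manifest = _toy_responses_and_manifest()
        with pytest.raises(ValueError, match="unknown channel"):
            channel_series(responses, manifest, "Q", instrument="fl")


class TestTrendStats:
    def _points(self, des_by_stage):
        recs = [
            {"subject_id": "a", "ref": 1, "stage": s, "de": d}
            for s, ds in des_by_stage.items()
            for d in ds
        ]
        return pd.DataFrame(recs)

    def test_flat_curve(self):
        pts = self._points({s: [5.0] for s in range(7)})
        slope, rng_ = trend_stats(pts, "overall")
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert rng_ == pytest.approx(0.0, abs=1e-12)

    def test_identity_curve_slope_one(self):
        pts = self._points({s: [float(s)] for s in range(7)})
        slope, rng_ = trend_stats(pts, "overall")
        assert slope == pytest.approx(1.0)
        assert rng_ == pytest.approx(6.0)

    def test_morphed_only_restricts_stages(self):
        des = {0: [100.0], 6: [100.0], **{s: [float(s)] for s in range(1, 6)}}
        slope, rng_ = trend_stats(self._points(des), "morphed_only")
        assert slope == pytest.approx(1.0)
        assert rng_ == pytest.approx(4.0)

    def test_slope_invariant_under_constant_shift(self):
        pts = self._points({s: [2.0 * s + 1.0] for s in range(7)})
        shifted = pts.assign(de=pts["de"] + 17.0)
        assert trend_stats(pts)[0] == pytest.approx(trend_stats(shifted)[0])

    def test_fewer_than_two_stages_rejected(self):
        with pytest.raises(ValueError):
            trend_stats(self._points({3: [1.0, 2.0]}), "overall")

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(-30, 30), st.floats(0, 40))
    def test_slope_recovers_planted_line(self, slope_true, intercept):
        pts = self._points({s: [slope_true * s + intercept] for s in range(7)})
        slope, _ = trend_stats(pts, "overall")
        assert slope == pytest.approx(slope_true, abs=1e-8)


class TestPublishedTrendTables:
    def test_slope_means_reproduce_printed_row(self):
        table = trend_slope_table()
        printed = {"syn_overall": 3.366, "non_overall": 3.965, "best_overall": 3.522,
                   "syn_morphed": 1.905, "non_morphed": 0.916, "best_morphed": 1.358}
        for col, want in printed.items():
            assert table[col].mean() == pytest.approx(want, abs=5e-4)

    def test_range_means_reproduce_printed_row(self):
        table = trend_range_table()
        printed = {"syn_overall": 33.9943, "non_overall": 45.53465, "best_overall": 42.7883,
                   "syn_morphed": 14.7138, "non_morphed": 11.9145, "best_morphed": 24.64655}
        for col, want in printed.items():
            assert table[col].mean() == pytest.approx(want, abs=5e-5)


class TestOnSimulatedCohort:
    def test_morph_curves_rise_toward_target(self, responses, manifest, synesthete_ids):
        trend = morph_distance_curves(responses, manifest, "piano", "flute", synesthete_ids)
        assert trend.slope_overall > 0
        assert trend.curve.loc[6] > trend.curve.loc[0]
        assert trend.range_overall >= trend.range_morphed_only >= 0

    def test_group_trend_table_shape_and_mean(self, responses, manifest, synesthete_ids):
        groups = {"syn": synesthete_ids}
        slopes, ranges = group_trend_table(responses, manifest, groups)
        assert list(slopes.index[:-1]) == ["flute>piano", "piano>flute"]
        assert slopes.loc["Mean", "syn_overall"] == pytest.approx(
            slopes.iloc[:-1]["syn_overall"].mean()
        )
        assert (ranges.iloc[:-1] >= 0).all().all()

    def test_single_pair_mean_equals_pair(self, responses, manifest, synesthete_ids):
        slopes, _ = group_trend_table(
            responses, manifest, {"syn": synesthete_ids}, pairs=["piano>flute"]
        )
        assert slopes.loc["Mean", "syn_overall"] == pytest.approx(
            slopes.loc["piano>flute", "syn_overall"]
        )

    def test_feature_correlations_tidy_output(self, responses, manifest, features_table, synesthete_ids):
        out = feature_correlations(
            responses, manifest, features_table, subjects=synesthete_ids,
            instruments=["flute"], group="syn",
        )
        assert len(out) == 5 * 3  # channels × features
        assert set(out["channel"]) == {"S", "L", "R", "G", "B"}
        assert ((out["r"] <= 1.0) & (out["r"] >= -1.0)).all()
        assert (out["n"] == 11).all()  # levels 0..10
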