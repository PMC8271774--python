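"""Paired comparisons, star coding, grids, regression, HRV contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from micromotion import (
    collapsed_comparison,
    compare_cell,
    comparison_grid,
    factor_regression,
    hrv_comparison,
    stars_from_p,
)
from micromotion.au import au_definitions

SECTIONS = ("t+0.5", "t+1", "t+4")


def make_feature_df(
    n_subjects=20,
    emotions=("happiness",),
    effects=None,
    noise=0.1,
    seed=0,
):
    """Synthetic long-format feature table.

    ``effects`` maps (feature, side or None) -> additive shift applied to
    the real condition; subjects carry a shared random offset so the
    paired design is informative.
    """
    rng = np.random.default_rng(seed)
    effects = effects or {}
    rows = []
    for subject in range(n_subjects):
        subj_offset = rng.normal(0, 0.2)
        for emotion in emotions:
            for authenticity in ("real", "fake"):
                for d in au_definitions():
                    for section in SECTIONS:
                        base = {"mean_delta": 1.0, "sd_delta": 0.5, "dominant_peak_hz": 8.0}
                        row = {
                            "subject": subject,
                            "emotion": emotion,
                            "authenticity": authenticity,
                            "au": d.name,
                            "side": d.side,
                            "section": section,
                            "truncated": False,
                        }
                        for feat, val in base.items():
                            shift = 0.0
                            if authenticity == "real":
                                shift += effects.get((feat, None), 0.0)
                                shift += effects.get((feat, d.side), 0.0)
                            row[feat] = val + subj_offset + shift + rng.normal(0, noise)
                        rows.append(row)
    return pd.DataFrame(rows)


class TestStarCoding:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.0005, "***"),
            (0.001, "**"),
            (0.005, "**"),
            (0.01, "*"),
            (0.049, "*"),
            (0.05, "ns"),
            (0.5, "ns"),
            (float("nan"), "ns"),
        ],
    )
    def test_three_level_mapping_with_strict_boundaries(self, p, expected):
        assert stars_from_p(p) == expected


class TestCompareCell:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        cell = compare_cell(x, x.copy())
        assert cell.t_stat == 0.0
        assert cell.p_value == 1.0
        assert cell.stars == "ns" and cell.direction == "none"

    def test_zero_variance_paired_differences_not_computable(self):
        real = np.array([1.0, 2.0, 3.0])
        cell = compare_cell(real, real - 0.5)
        assert not cell.computable
        assert np.isnan(cell.p_value)

    def test_insufficient_n(self):
        cell = compare_cell(np.array([1.0, 2.0]), np.array([0.5, 0.1]))
        assert not cell.computable

    def test_matches_scipy_paired_ttest(self, rng):
        real = rng.normal(1.0, 1.0, 30)
        fake = rng.normal(0.5, 1.0, 30)
        cell = compare_cell(real, fake)
        t, p = spstats.ttest_rel(real, fake)
        assert cell.t_stat == pytest.approx(t)
        assert cell.p_value == pytest.approx(p)

    def test_power_against_monte_carlo_oracle(self):
        # paired n=40 samples from N(1,1) vs N(1.8,1) with correlation 0.5
        # must reject at alpha=0.05 in > 90% of 500 replicates
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(500):
            shared = rng.normal(0, np.sqrt(0.5), 40)
            real = 1.0 + shared + rng.normal(0, np.sqrt(0.5), 40)
            fake = 1.8 + shared + rng.normal(0, np.sqrt(0.5), 40)
            if compare_cell(real, fake).p_value < 0.05:
                rejections += 1
        assert rejections / 500 > 0.90


class TestComparisonGrid:
    def test_cell_counts(self):
        df = make_feature_df(emotions=("happiness", "anger", "contentment", "sadness"))
        cells, grid = comparison_grid(df)
        assert len(cells) == 396  # 4 emotions x 11 AUs x 3 sections x 3 features
        assert (cells.groupby("emotion").size() == 99).all()
        for slots in grid["emotions"].values():
            assert len(slots) == 11

    def test_left_side_effect_concentrates_stars_left(self):
        df = make_feature_df(
            n_subjects=30,
            effects={("mean_delta", "left"): 1.0, ("sd_delta", "left"): 0.8},
            seed=3,
        )
        cells, _ = comparison_grid(df)
        strong = cells[cells.p_value < 0.001]
        assert len(strong) > 0
        assert (strong.side == "left").all()

    def test_missing_condition_skips_emotion(self):
        df = make_feature_df()
        df = df[df.authenticity == "real"]
        with pytest.warns(UserWarning, match="lacks"):
            cells, _ = comparison_grid(df)
        assert len(cells) == 0


class TestCollapsed:
    def test_programmed_directions(self):
        df = make_feature_df(
            n_subjects=30,
            effects={("mean_delta", None): 0.8, ("dominant_peak_hz", None): -2.0},
            seed=4,
        )
        out = collapsed_comparison(df)
        by_feat = out.set_index("feature")
        assert by_feat.loc["mean_delta", "direction"] == "real>fake"
        assert by_feat.loc["dominant_peak_hz", "direction"] == "fake>real"

    def test_identical_conditions_direction_none(self):
        df = make_feature_df(noise=0.1, seed=5)
        out = collapsed_comparison(df)
        # no programmed effect: large-p cells must read "none"
        assert (out.loc[out.p_value >= 0.05, "direction"] == "none").all()


class TestFactorRegression:
    @staticmethod
    def _additive_df(n_subjects=15, auth_effect=0.5, seed=0):
        rng = np.random.default_rng(seed)
        df = make_feature_df(n_subjects=n_subjects, seed=seed, noise=0.0)
        section_eff = {"t+0.5": 0.0, "t+1": 0.6, "t+4": 1.5}
        side_eff = {"left": 0.3, "right": 0.0, "middle": 0.1}
        df["mean_delta"] = (
            1.0
            + df["section"].map(section_eff)
            + df["side"].map(side_eff)
            + np.where(df["authenticity"] == "real", auth_effect, 0.0)
            + rng.normal(0, 0.05, len(df))
        )
        return df

    def test_recovers_additive_factor_structure(self):
        res = factor_regression(self._additive_df(), "happiness")
        assert res.r_squared > 0.9
        assert all(p < 0.001 for p in res.factor_pvalues.values())

    def test_null_authenticity_factor_rarely_significant(self):
        hits = 0
        reps = 60
        for rep in range(reps):
            df = self._additive_df(n_subjects=8, auth_effect=0.0, seed=100 + rep)
            res = factor_regression(df, "happiness")
            if res.factor_pvalues["authenticity"] < 0.05:
                hits += 1
        assert hits / reps <= 0.10

    def test_constant_response_flagged_degenerate(self):
        df = make_feature_df(noise=0.0, seed=1)
        df["mean_delta"] = 2.0
        res = factor_regression(df, "happiness")
        assert res.degenerate and res.r_squared == 0.0

    def test_missing_factor_level_rejected(self):
        df = make_feature_df()
        df = df[df.section == "t+1"]
        with pytest.raises(ValueError, match="section"):
            factor_regression(df, "happiness")


class TestHRVComparison:
    @staticmethod
    def _hrv_df(hf_shift=0.0, n=25, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for subject in range(n):
            base = rng.normal(0, 10)
            for auth in ("real", "fake"):
                vlf = 400 + base + rng.normal(0, 20)
                lf = 300 + base + rng.normal(0, 20)
                hf = 300 + base + rng.normal(0, 20) + (hf_shift if auth == "fake" else 0)
                total = vlf + lf + hf
                rows.append(
                    {
                        "subject": subject,
                        "authenticity": auth,
                        "vlf": vlf,
                        "lf": lf,
                        "hf": hf,
                        "vlf_pct": 100 * vlf / total,
                        "lf_pct": 100 * lf / total,
                        "hf_pct": 100 * hf / total,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_conditions_all_ns(self):
        out = hrv_comparison(self._hrv_df(hf_shift=0.0, seed=6))
        assert set(out["feature"]) == {"vlf", "lf", "hf", "vlf_pct", "lf_pct", "hf_pct"}
        # directions may fluctuate, but nothing should be strongly significant
        assert (out["p_value"] > 0.001).all()

    def test_hf_only_shift_localised(self):
        out = hrv_comparison(self._hrv_df(hf_shift=150.0, seed=7)).set_index("feature")
        assert out.loc["hf", "direction"] == "fake>real"
        assert out.loc["hf", "stars"] != "ns"
        assert out.loc["lf", "stars"] == "ns"


class TestFaceGridRendering:
    def test_renders_one_panel_per_emotion(self, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        from micromotion.viz import render_face_grid

        df = make_feature_df(emotions=("happiness", "anger"), seed=8)
        cells, _ = comparison_grid(df)
        out = tmp_path / "grid.png"
        fig = render_face_grid(cells, path=str(out), feature="mean_delta")
        assert out.exists() and out.stat().st_size > 0
        assert len(fig.axes) == 2
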