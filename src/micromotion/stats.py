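"""Real-vs-fake statistical comparison of micromovement features.

The experimental design is 2 (authenticity: real, fake) x 4 (emotion)
within-subject, so every comparison defaults to a paired t-test on the
per-subject feature values.  Significance is coded at three levels
(p < 0.001 ***, p < 0.01 **, p < 0.05 *; boundary values are ns) with no
multiple-testing correction by default, mirroring the star-grid style of
reporting; a Benjamini-Hochberg option is available.  Comparisons are
produced per AU x section x feature (the face-grid report), collapsed
across sections and AUs per emotion, and for the six HRV variables.  A
linear factor model of average movement on the section, authenticity and
face-side factors summarises which design factors drive movement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .au import au_definitions
from .features import FEATURE_NAMES
from .hrv import HRV_VARIABLES

__all__ = [
    "ComparisonCell",
    "RegressionResult",
    "stars_from_p",
    "compare_cell",
    "comparison_grid",
    "collapsed_comparison",
    "factor_regression",
    "hrv_comparison",
    "POST_SECTION_NAMES",
]

POST_SECTION_NAMES = ("t+0.5", "t+1", "t+4")

ALPHA = 0.05


def stars_from_p(p: float) -> str:
    """Three-level significance code; boundary p-values fall in ``ns``."""
    if not np.isfinite(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ComparisonCell:
    """One real-vs-fake test: a feature of one AU in one section."""

    emotion: str | None
    au: str | None
    side: str | None
    section: str | None
    feature: str
    n: int
    t_stat: float
    p_value: float
    mean_real: float
    mean_fake: float
    direction: str  # "real>fake" | "fake>real" | "none"
    stars: str
    computable: bool = True
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "emotion": self.emotion,
            "au": self.au,
            "side": self.side,
            "section": self.section,
            "feature": self.feature,
            "n": self.n,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "mean_real": self.mean_real,
            "mean_fake": self.mean_fake,
            "direction": self.direction,
            "stars": self.stars,
            "computable": self.computable,
            "note": self.note,
        }


def _direction(mean_real: float, mean_fake: float, p: float, alpha: float = ALPHA) -> str:
    if not np.isfinite(p) or p >= alpha or mean_real == mean_fake:
        return "none"
    return "real>fake" if mean_real > mean_fake else "fake>real"


def compare_cell(
    real_values: np.ndarray,
    fake_values: np.ndarray,
    paired: bool = True,
    emotion: str | None = None,
    au: str | None = None,
    side: str | None = None,
    section: str | None = None,
    feature: str = "",
) -> ComparisonCell:
    """Two-sided t-test of a feature between the real and fake conditions.

    Paired by default (within-subject design; inputs must be aligned by
    subject).  Cells with fewer than 3 observations per condition, or
    with zero-variance paired differences, are marked not-computable
    rather than reporting a spurious p-value.
    """
    real = np.asarray(real_values, dtype=float)
    fake = np.asarray(fake_values, dtype=float)
    if paired:
        if real.shape != fake.shape:
            raise ValueError("paired comparison needs equal-length aligned samples")
        keep = np.isfinite(real) & np.isfinite(fake)
        real, fake = real[keep], fake[keep]
    else:
        real, fake = real[np.isfinite(real)], fake[np.isfinite(fake)]
    n = min(real.size, fake.size)

    def _cell(t, p, computable=True, note=""):
        mr = float(real.mean()) if real.size else np.nan
        mf = float(fake.mean()) if fake.size else np.nan
        p = float(p)
        return ComparisonCell(
            emotion=emotion,
            au=au,
            side=side,
            section=section,
            feature=feature,
            n=n,
            t_stat=float(t),
            p_value=p,
            mean_real=mr,
            mean_fake=mf,
            direction=_direction(mr, mf, p) if computable else "none",
            stars=stars_from_p(p) if computable else "ns",
            computable=computable,
            note=note,
        )

    if real.size < 3 or fake.size < 3:
        return _cell(np.nan, np.nan, computable=False, note="insufficient n")
    if paired:
        diffs = real - fake
        if np.all(diffs == diffs[0]):
            if diffs[0] == 0.0:
                # identical samples: no difference at all
                return _cell(0.0, 1.0, note="identical samples")
            return _cell(np.nan, np.nan, computable=False, note="zero-variance paired differences")
        t, p = spstats.ttest_rel(real, fake)
    else:
        if real.std() == 0 and fake.std() == 0:
            if real.mean() == fake.mean():
                return _cell(0.0, 1.0, note="identical samples")
            return _cell(np.nan, np.nan, computable=False, note="zero within-condition variance")
        t, p = spstats.ttest_ind(real, fake)
    return _cell(t, p)


def _paired_pivot(df: pd.DataFrame, value: str) -> tuple[np.ndarray, np.ndarray]:
    """Align per-subject values of the two conditions; returns (real, fake)."""
    wide = df.pivot_table(index="subject", columns="authenticity", values=value, aggfunc="mean")
    if "real" not in wide or "fake" not in wide:
        raise KeyError("both conditions required")
    return wide["real"].to_numpy(), wide["fake"].to_numpy()


def comparison_grid(
    features: pd.DataFrame,
    paired: bool = True,
    include_truncated: bool = False,
    fdr: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-emotion grid of real-vs-fake cells and its face-grid layout.

    For every emotion x AU x post-onset section x feature the two
    conditions are compared across subjects (11 AUs x 3 sections x
    3 features = 99 cells per emotion).  Returns a tidy cell table and a
    JSON-able face-grid structure with one slot per AU (placed by face
    side) listing the significance stars per section and feature.
    Emotions missing a condition are skipped with a warning.  ``fdr``
    applies a Benjamini-Hochberg correction within each emotion before
    star coding.
    """
    df = features.copy()
    if not include_truncated:
        df = df[~df["truncated"].astype(bool)]
    df = df[df["section"].isin(POST_SECTION_NAMES)]

    cells: list[ComparisonCell] = []
    for emotion, emo_df in df.groupby("emotion", sort=True):
        if emo_df["authenticity"].nunique() < 2:
            warnings.warn(f"emotion {emotion!r} lacks one condition; skipped", stacklevel=2)
            continue
        for (au, side), au_df in emo_df.groupby(["au", "side"], sort=True):
            for section in POST_SECTION_NAMES:
                sec_df = au_df[au_df["section"] == section]
                for feature in FEATURE_NAMES:
                    try:
                        real, fake = _paired_pivot(sec_df, feature)
                    except KeyError:
                        real = fake = np.array([])
                    cells.append(
                        compare_cell(
                            real,
                            fake,
                            paired=paired,
                            emotion=emotion,
                            au=au,
                            side=side,
                            section=section,
                            feature=feature,
                        )
                    )
    columns = list(ComparisonCell.__dataclass_fields__)
    table = pd.DataFrame([c.as_dict() for c in cells], columns=columns)
    if fdr and len(table):
        from statsmodels.stats.multitest import multipletests

        for emotion in table["emotion"].unique():
            m = (table["emotion"] == emotion) & table["computable"]
            if m.sum():
                _, p_adj, _, _ = multipletests(table.loc[m, "p_value"], method="fdr_bh")
                table.loc[m, "p_value"] = p_adj
                table.loc[m, "stars"] = [stars_from_p(p) for p in p_adj]
    return table, face_grid(table)


def face_grid(cell_table: pd.DataFrame) -> dict:
    """Face-grid report: 11 AU slots (left/right/middle) with star codes.

    Mirrors the visual reporting template in which each AU occupies a
    slot on a schematic face and is coloured by significance level.
    """
    slot_order = [d.name for d in au_definitions()]
    grid: dict = {"emotions": {}}
    if not len(cell_table):
        return grid
    for emotion, emo_df in cell_table.groupby("emotion", sort=True):
        slots = []
        for au in slot_order:
            au_df = emo_df[emo_df["au"] == au]
            if not len(au_df):
                continue
            slots.append(
                {
                    "au": au,
                    "side": au_df["side"].iloc[0],
                    "cells": [
                        {
                            "section": r.section,
                            "feature": r.feature,
                            "stars": r.stars,
                            "direction": r.direction,
                        }
                        for r in au_df.itertuples()
                    ],
                }
            )
        grid["emotions"][emotion] = slots
    return grid


def collapsed_comparison(features: pd.DataFrame, paired: bool = True) -> pd.DataFrame:
    """Condition summary per emotion x feature, pooled over sections and AUs.

    Each subject contributes one value per condition (the mean over the
    three post-onset sections and all AUs), and the conditions are
    compared with a paired test — the collapsed companion to the per-AU
    grid.
    """
    df = features[~features["truncated"].astype(bool)]
    df = df[df["section"].isin(POST_SECTION_NAMES)]
    rows = []
    for emotion, emo_df in df.groupby("emotion", sort=True):
        if emo_df["authenticity"].nunique() < 2:
            warnings.warn(f"emotion {emotion!r} lacks one condition; skipped", stacklevel=2)
            continue
        for feature in FEATURE_NAMES:
            real, fake = _paired_pivot(emo_df, feature)
            cell = compare_cell(real, fake, paired=paired, emotion=emotion, feature=feature)
            rows.append(cell.as_dict())
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    """Linear factor model of average movement for one emotion."""

    emotion: str
    r_squared: float
    nobs: int
    coefficients: dict = field(default_factory=dict)
    factor_pvalues: dict = field(default_factory=dict)
    degenerate: bool = False


def factor_regression(features: pd.DataFrame, emotion: str) -> RegressionResult:
    """OLS of mean movement on the section, authenticity and side factors.

    Fits ``mean_delta ~ C(section) + C(authenticity) + C(side)`` (main
    effects, fitted simultaneously) on the post-onset rows of one
    emotion and reports R^2, coefficients and per-factor p-values from a
    type-II ANOVA.  A constant response is flagged degenerate (R^2 = 0).
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = features[(features["emotion"] == emotion) & ~features["truncated"].astype(bool)]
    df = df[df["section"].isin(POST_SECTION_NAMES)].dropna(subset=["mean_delta"])
    if not len(df):
        raise ValueError(f"no usable rows for emotion {emotion!r}")
    for factor in ("section", "authenticity", "side"):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    if df["mean_delta"].nunique() == 1:
        return RegressionResult(emotion=emotion, r_squared=0.0, nobs=len(df), degenerate=True)
    model = smf.ols(
        "mean_delta ~ C(section) + C(authenticity) + C(side)", data=df
    ).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anova = anova_lm(model, typ=2)
    pvals = {
        name.replace("C(", "").replace(")", ""): float(p)
        for name, p in anova["PR(>F)"].items()
        if name != "Residual"
    }
    return RegressionResult(
        emotion=emotion,
        r_squared=float(model.rsquared),
        nobs=int(model.nobs),
        coefficients={k: float(v) for k, v in model.params.items()},
        factor_pvalues=pvals,
    )


def hrv_comparison(hrv_table: pd.DataFrame, paired: bool = True) -> pd.DataFrame:
    """Real-vs-fake comparison of the six HRV variables.

    ``hrv_table`` needs one row per subject x condition with columns
    ``subject``, ``authenticity`` and the six band variables (vlf, lf,
    hf and their percentages).
    """
    rows = []
    for variable in HRV_VARIABLES:
        real, fake = _paired_pivot(hrv_table, variable)
        cell = compare_cell(real, fake, paired=paired, feature=variable)
        rows.append(cell.as_dict())
    return pd.DataFrame(rows)
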