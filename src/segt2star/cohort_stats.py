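"""Normative summaries and covariate analyses for segmental T2* cohorts.

Per-subject scalars (global T2*, slice means, single segments) are
summarised overall or stratified by age decade, sex, or short-axis
slice.  Covariate analyses follow the common normality-gated pattern:
Shapiro-Wilk decides between Pearson and Spearman correlation and
between the unpaired Student t-test and the Mann-Whitney test; the
multivariable analysis is an ordinary least-squares linear model with
age, sex, and (where available) wall thickness as predictors,
Bonferroni-corrected across the responses tested in one call.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .published import SLICE_SEGMENTS
from .correction import t2star_matrix

logger = logging.getLogger(__name__)

_DEFAULT_AGE_BINS = ((20, 30), (30, 40), (40, 50), (50, 60), (60, 70))


def global_values(cohort: pd.DataFrame) -> pd.Series:
    """Per-subject global T2* (ms): arithmetic mean of the 16 segments."""
    return pd.Series(
        t2star_matrix(cohort).mean(axis=1), index=cohort.index, name="global_t2star"
    )


def slice_values(cohort: pd.DataFrame, level: str) -> pd.Series:
    """Per-subject mean T2* (ms) of one short-axis slice level."""
    segs = SLICE_SEGMENTS[level]
    cols = [f"t2s_seg{k:02d}" for k in segs]
    return pd.Series(
        cohort[cols].to_numpy(dtype=float).mean(axis=1),
        index=cohort.index,
        name=f"{level}_t2star",
    )


def normative_summary(
    cohort: pd.DataFrame,
    stratify_by: str = "none",
    value: str = "global",
    age_bins=_DEFAULT_AGE_BINS,
) -> pd.DataFrame:
    """Mean ± SD table of a per-subject scalar, optionally stratified.

    ``stratify_by`` is one of ``none``, ``age_bin``, ``sex`` or
    ``slice``; ``value`` is ``global``, a slice level, or ``seg<k>``.
    For ``slice`` stratification the strata are the three slice levels
    themselves (each subject contributes its slice mean to every
    stratum).  Empty strata are reported with n = 0 and no statistics.
    """
    if value == "global":
        scalar = global_values(cohort)
    elif value in SLICE_SEGMENTS:
        scalar = slice_values(cohort, value)
    elif value.startswith("seg"):
        scalar = cohort[f"t2s_seg{int(value[3:]):02d}"].astype(float)
    else:
        raise ValueError(f"unknown value {value!r}")

    def _row(label: str, vals: np.ndarray) -> dict:
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            return {"stratum": label, "n": 0, "mean": np.nan, "sd": np.nan}
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return {"stratum": label, "n": len(vals), "mean": float(vals.mean()), "sd": sd}

    rows = []
    if stratify_by == "none":
        rows.append(_row("all", scalar.to_numpy()))
    elif stratify_by == "age_bin":
        ages = cohort["age_years"].to_numpy(dtype=float)
        for i, (lo, hi) in enumerate(age_bins):
            last = i == len(age_bins) - 1
            sel = (ages >= lo) & ((ages <= hi) if last else (ages < hi))
            rows.append(_row(f"{lo}-{hi - 1}", scalar.to_numpy()[sel]))
    elif stratify_by == "sex":
        for s in ("M", "F"):
            rows.append(_row(s, scalar.to_numpy()[cohort["sex"].to_numpy() == s]))
    elif stratify_by == "slice":
        for level in SLICE_SEGMENTS:
            rows.append(_row(level, slice_values(cohort, level).to_numpy()))
    else:
        raise ValueError(f"unknown stratification {stratify_by!r}")
    return pd.DataFrame(rows).set_index("stratum")


def correlate(x, y, method: str = "auto") -> tuple[float, float, str]:
    """Correlation (r, p, method used) with a normality gate.

    ``auto`` picks Pearson when Shapiro-Wilk does not reject normality
    for either variable (alpha 0.05), Spearman otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need >=3 complete (x, y) pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    if method == "auto":
        normal = (
            stats.shapiro(x).pvalue >= 0.05 and stats.shapiro(y).pvalue >= 0.05
        )
        method = "pearson" if normal else "spearman"
        logger.info("correlation gate selected %s", method)
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), method


def group_compare(a, b, alpha: float = 0.05) -> tuple[float, str]:
    """Two-group comparison (p, test used) with a normality gate.

    Student's unpaired t-test when both groups pass Shapiro-Wilk,
    Mann-Whitney otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need >=3 values")
    if np.std(a) == 0 and np.std(b) == 0 and a[0] == b[0]:
        return 1.0, "degenerate"
    normal = stats.shapiro(a).pvalue >= alpha and stats.shapiro(b).pvalue >= alpha
    if normal:
        return float(stats.ttest_ind(a, b, equal_var=True).pvalue), "student_t"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue), "mann_whitney"


def multivariable_model(
    cohort: pd.DataFrame,
    responses: list[str] | None = None,
) -> pd.DataFrame:
    """OLS of T2* on age, sex and wall thickness, per response.

    ``responses`` are segment names (``seg7`` ... ``seg12``) or
    ``global``; wall thickness enters only for mid-ventricular segments
    where a matching ``wt_seg..`` column exists.  Returns a coefficient
    table with p-values Bonferroni-corrected across the responses tested
    in this call.  Also reports each model's overall F-test p-value.
    """
    if responses is None:
        responses = [f"seg{k}" for k in range(7, 13)]
    m = len(responses)
    sex01 = (cohort["sex"].to_numpy() == "M").astype(float)
    rows = []
    for resp in responses:
        if resp == "global":
            y = global_values(cohort).to_numpy()
            wt = None
        else:
            k = int(resp[3:])
            y = cohort[f"t2s_seg{k:02d}"].to_numpy(dtype=float)
            wt_col = f"wt_seg{k:02d}"
            wt = (
                cohort[wt_col].to_numpy(dtype=float)
                if wt_col in cohort.columns
                else None
            )
        X = pd.DataFrame(
            {"age": cohort["age_years"].to_numpy(dtype=float), "sex_male": sex01}
        )
        if wt is not None:
            X["wall_thickness"] = wt
        X = sm.add_constant(X)
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            logger.warning("rank-deficient design for %s; skipped", resp)
            rows.append(
                {"response": resp, "term": "rank_deficient", "coef": np.nan,
                 "p": np.nan, "p_bonferroni": np.nan, "model_f_p": np.nan}
            )
            continue
        fit = sm.OLS(y, X).fit()
        for term in X.columns:
            if term == "const":
                continue
            p = float(fit.pvalues[term])
            rows.append(
                {
                    "response": resp,
                    "term": term,
                    "coef": float(fit.params[term]),
                    "p": p,
                    "p_bonferroni": min(1.0, m * p),
                    "model_f_p": float(fit.f_pvalue),
                }
            )
    return pd.DataFrame(rows)


def segment_ranges(cohort: pd.DataFrame) -> pd.Series:
    """Per-segment max - min T2* (ms) across subjects."""
    t2 = t2star_matrix(cohort)
    return pd.Series(
        t2.max(axis=0) - t2.min(axis=0),
        index=pd.RangeIndex(1, 17, name="segment"),
        name="range_ms",
    )
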