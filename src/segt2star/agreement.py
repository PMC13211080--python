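"""Reproducibility statistics for repeated T2* measurements.

Implements the usual test-retest toolkit: paired difference tests with a
Shapiro-Wilk normality gate (paired t when the differences look normal,
Wilcoxon signed-rank otherwise), Bland-Altman bias and 95% limits of
agreement (bias +/- 1.96 SD of the differences), and the intraclass
correlation coefficient ICC(2,1) — two-way random effects, absolute
agreement, single measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

logger = logging.getLogger(__name__)

ICC_BANDS = ((0.75, "excellent"), (0.60, "good"), (0.40, "fair"), (-np.inf, "poor"))


@dataclass(frozen=True)
class PairedMeasurements:
    """Aligned repeat measurements (ms) of the same units."""

    first: np.ndarray
    second: np.ndarray
    context: str = "inter_study"  # or intra_operator / inter_operator

    def __post_init__(self) -> None:
        a = np.asarray(self.first, dtype=float)
        b = np.asarray(self.second, dtype=float)
        if a.ndim != 1 or a.shape != b.shape:
            raise ValueError("first and second must be 1-D of equal length")
        if len(a) < 3:
            raise ValueError("need at least 3 pairs")
        if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
            raise ValueError("missing pairs are not allowed")
        object.__setattr__(self, "first", a)
        object.__setattr__(self, "second", b)

    @property
    def differences(self) -> np.ndarray:
        return self.second - self.first


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    sd: float
    lower: float
    upper: float


@dataclass(frozen=True)
class AgreementResult:
    """Summary of one reproducibility comparison."""

    mean_difference: float
    sd_difference: float
    p_value: float
    test_used: str
    limits: BlandAltman
    icc_value: float | None = None


def paired_difference_test(
    pairs: PairedMeasurements, alpha: float = 0.05
) -> tuple[float, str]:
    """Two-tailed p for a systematic difference between repeats.

    Shapiro-Wilk on the differences at ``alpha`` gates the choice:
    paired t-test when normality is not rejected, Wilcoxon signed-rank
    otherwise.  Zero-variance differences are degenerate and reported as
    (1.0, "degenerate").
    """
    d = pairs.differences
    if np.allclose(d, d[0]):
        if d[0] != 0:
            logger.warning("constant nonzero differences; test degenerate")
        return 1.0, "degenerate"
    normal = stats.shapiro(d).pvalue >= alpha
    if normal:
        p = stats.ttest_rel(pairs.second, pairs.first).pvalue
        return float(p), "paired_t"
    p = stats.wilcoxon(pairs.second, pairs.first, method="auto").pvalue
    return float(p), "wilcoxon"


def bland_altman(pairs: PairedMeasurements) -> BlandAltman:
    """Bias and 95% limits of agreement (bias +/- 1.96 SD)."""
    d = pairs.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, sd=sd, lower=bias - 1.96 * sd, upper=bias + 1.96 * sd)


def icc(matrix) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``matrix`` is units x raters/sessions with no missing cells.
    A constant matrix has no between-unit variance to apportion and is
    rejected as undefined.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("need a units x raters matrix, >=3 units, >=2 raters")
    if np.any(~np.isfinite(m)):
        raise ValueError("missing cells are not allowed")
    if np.allclose(m, m.flat[0]):
        raise ValueError("ICC undefined for a constant matrix")
    n, k = m.shape
    long = pd.DataFrame(
        {
            "target": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": m.ravel(),
        }
    )
    table = pg.intraclass_corr(
        data=long, targets="target", raters="rater", ratings="score"
    )
    # two-way random, absolute agreement, single measures: labelled
    # "ICC2" or "ICC(A,1)" depending on the pingouin version
    sel = table["Type"].isin(["ICC2", "ICC(A,1)"])
    return float(table.loc[sel, "ICC"].iloc[0])


def icc_classification(value: float) -> str:
    """Qualitative band for an ICC (>0.75 excellent ... <0.40 poor)."""
    for lo, label in ICC_BANDS:
        if value >= lo:
            return label
    raise AssertionError("unreachable")


def assess_agreement(pairs: PairedMeasurements, alpha: float = 0.05) -> AgreementResult:
    """Full reproducibility summary for one paired comparison."""
    p, test = paired_difference_test(pairs, alpha=alpha)
    ba = bland_altman(pairs)
    matrix = np.column_stack([pairs.first, pairs.second])
    try:
        icc_val: float | None = icc(matrix)
    except ValueError:
        icc_val = None
    return AgreementResult(
        mean_difference=ba.bias,
        sd_difference=ba.sd,
        p_value=p,
        test_used=test,
        limits=ba,
        icc_value=icc_val,
    )


def simulate_repeat_study(
    cohort: pd.DataFrame,
    noise_sd_ms: float,
    seed: int,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Re-measure a cohort with independent Gaussian measurement noise.

    Emulates a second scan (or a second reading) of the same subjects:
    each segmental T2* value gets an independent N(0, noise_sd_ms) error.
    """
    if noise_sd_ms < 0:
        raise ValueError("noise SD must be non-negative")
    cols = columns or [f"t2s_seg{k:02d}" for k in range(1, 17)]
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    vals = out[cols].to_numpy(dtype=float)
    out[cols] = np.clip(vals + rng.normal(0.0, noise_sd_ms, vals.shape), 0.1, None)
    return out
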