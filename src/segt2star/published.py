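"""Published reference tables for the segmental T2* analysis.

Two healthy-cohort segmental summaries are carried as package constants:

* ``CVI_SUMMARY`` — the black-blood multi-echo gradient-echo cohort
  (n = 50, sex- and age-balanced, 1.5 T) analysed with commercial
  software; its ``mean_r2star``/``sd_r2star`` columns are the population
  parameters used by the synthetic generator, and its
  ``correction_factor`` column is the published segmental ΔR2* map.
* ``HIPPO_SUMMARY`` — the earlier white-blood cohort (n = 22) behind the
  HIPPO MIOT software, the published comparator.

All R2* quantities are in Hz, all T2* quantities in ms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: AHA 16-segment names, index 0 == segment 1.
AHA_SEGMENT_NAMES: tuple[str, ...] = (
    "basal anterior",
    "basal anteroseptal",
    "basal inferoseptal",
    "basal inferior",
    "basal inferolateral",
    "basal anterolateral",
    "mid anterior",
    "mid anteroseptal",
    "mid inferoseptal",
    "mid inferior",
    "mid inferolateral",
    "mid anterolateral",
    "apical anterior",
    "apical septal",
    "apical inferior",
    "apical lateral",
)

#: Mid-ventricular septal segments used as the artifact-free reference.
MIDSEPTAL_SEGMENTS: tuple[int, int] = (8, 9)

#: Segments per short-axis slice level.
SLICE_SEGMENTS: dict[str, tuple[int, ...]] = {
    "basal": (1, 2, 3, 4, 5, 6),
    "mid": (7, 8, 9, 10, 11, 12),
    "apical": (13, 14, 15, 16),
}

# segment, ΔR2* cvi, ΔR2* HIPPO, R2* cvi mean/SD, R2* HIPPO mean/SD,
# printed raw p, printed Bonferroni p (NaN where printed "ns")
_TABLE = [
    (1, 1.03, 4.7, 29.0, 4.3, 32.0, 7.9, 0.04, np.nan),
    (2, 0.34, -0.7, 28.3, 4.5, 26.6, 5.0, 0.16, np.nan),
    (3, -0.54, -1.0, 27.4, 4.1, 26.4, 3.8, 0.33, np.nan),
    (4, 7.29, 7.7, 35.3, 7.2, 35.1, 8.2, 0.92, np.nan),
    (5, 8.31, 3.3, 36.3, 7.6, 30.7, 5.9, 0.0031, 0.0496),
    (6, 1.36, -2.3, 29.3, 4.6, 25.0, 6.6, 0.0022, 0.0352),
    (7, 1.22, 6.9, 29.2, 4.4, 34.3, 6.5, 0.0002, 0.0032),
    (8, 0.51, 0.3, 28.5, 4.5, 27.6, 5.4, 0.46, np.nan),
    (9, -0.51, -0.3, 27.5, 4.3, 27.1, 7.0, 0.77, np.nan),
    (10, 0.66, 4.6, 28.6, 5.3, 32.0, 6.3, 0.02, np.nan),
    (11, 8.11, 0.6, 36.1, 8.5, 28.0, 6.3, 0.0002, 0.0032),
    (12, 2.82, 1.3, 30.8, 4.0, 28.6, 3.7, 0.03, np.nan),
    (13, 5.62, 6.1, 33.6, 6.1, 33.5, 6.7, 0.95, np.nan),
    (14, -0.78, -2.2, 27.2, 4.8, 25.1, 5.1, 0.097, np.nan),
    (15, -1.45, -0.2, 26.5, 5.5, 27.1, 7.0, 0.7, np.nan),
    (16, 8.18, 2.2, 36.2, 8.0, 29.5, 6.6, 0.001, 0.016),
]

_df = pd.DataFrame(
    _TABLE,
    columns=[
        "segment",
        "factor_cvi",
        "factor_hippo",
        "r2_cvi_mean",
        "r2_cvi_sd",
        "r2_hippo_mean",
        "r2_hippo_sd",
        "p_printed",
        "p_bonferroni_printed",
    ],
).set_index("segment")

CVI_N = 50
HIPPO_N = 22


def _summary(prefix: str, n: int, label: str) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "aha_name": AHA_SEGMENT_NAMES,
            "n": n,
            "mean_r2star": _df[f"r2_{prefix}_mean"].to_numpy(),
            "sd_r2star": _df[f"r2_{prefix}_sd"].to_numpy(),
        },
        index=_df.index,
    )
    out.attrs["cohort"] = label
    return out


#: Segmental (n, mean R2*, SD R2*) summary of the commercial-software cohort.
CVI_SUMMARY: pd.DataFrame = _summary("cvi", CVI_N, "cvi")

#: Segmental summary of the published HIPPO comparison cohort.
HIPPO_SUMMARY: pd.DataFrame = _summary("hippo", HIPPO_N, "hippo")

#: Published segmental correction factors ΔR2* (Hz), index = segment 1..16.
CVI_FACTORS: pd.Series = _df["factor_cvi"].rename("delta_r2star_hz")
HIPPO_FACTORS: pd.Series = _df["factor_hippo"].rename("delta_r2star_hz")

#: Printed comparison p-values (raw and Bonferroni; NaN == not significant).
PRINTED_P: pd.Series = _df["p_printed"]
PRINTED_P_BONFERRONI: pd.Series = _df["p_bonferroni_printed"]

#: Mid-ventricular wall thickness (mm) by sex, segments 7–12: (male mean,
#: male SD, female mean, female SD).  Used by the synthetic generator.
WALL_THICKNESS_BY_SEX: dict[int, tuple[float, float, float, float]] = {
    7: (6.8, 1.1, 5.0, 1.3),
    8: (7.1, 1.2, 5.3, 1.0),
    9: (7.5, 1.2, 5.7, 0.8),
    10: (6.3, 1.3, 4.7, 1.1),
    11: (6.0, 1.3, 4.4, 1.0),
    12: (5.8, 1.0, 4.7, 0.8),
}
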