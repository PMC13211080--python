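"""Segmental R2* correction-factor map referenced to the mid-septum.

Healthy myocardium shows systematic segment-wise T2* fluctuations from
susceptibility and geometric artifacts.  The mid-ventricular septum
(AHA segments 8 and 9) is conventionally protected from these, so each
segment's average deviation from it defines a correction factor

    dR2*_k = (1/N) * sum_j (R2*_kj - R2*_ms,j)

estimated over a healthy cohort of N subjects.  Correcting a new
measurement subtracts the factor in the R2* (Hz) domain and reconverts
to T2* (ms): a positive factor raises the corrected T2*.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .published import AHA_SEGMENT_NAMES, MIDSEPTAL_SEGMENTS
from .relaxometry import r2star_to_t2star, t2star_to_r2star

logger = logging.getLogger(__name__)

_SEG_COLS = [f"t2s_seg{k:02d}" for k in range(1, 17)]


@dataclass(frozen=True)
class SubjectSegmentalRecord:
    """One subject's 16 segmental T2* values (ms) plus demographics."""

    subject_id: str
    age_years: float
    sex: str
    t2star_ms: np.ndarray  # (16,), segment k at index k-1
    wall_thickness_mm: dict[int, float] | None = None  # segments 7-12

    def __post_init__(self) -> None:
        v = np.asarray(self.t2star_ms, dtype=float)
        if v.shape != (16,):
            raise ValueError("record needs exactly 16 segmental T2* values")
        if np.any(~np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("segmental T2* values must be finite and positive")
        object.__setattr__(self, "t2star_ms", v)

    @classmethod
    def from_row(cls, row: pd.Series) -> "SubjectSegmentalRecord":
        wt = {
            k: float(row[f"wt_seg{k:02d}"])
            for k in range(7, 13)
            if f"wt_seg{k:02d}" in row.index
        }
        return cls(
            subject_id=str(row["subject_id"]),
            age_years=float(row["age_years"]),
            sex=str(row["sex"]),
            t2star_ms=row[_SEG_COLS].to_numpy(dtype=float),
            wall_thickness_mm=wt or None,
        )


def t2star_matrix(cohort: pd.DataFrame) -> np.ndarray:
    """(n_subjects, 16) array of segmental T2* values from a cohort table."""
    missing = [c for c in _SEG_COLS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing segment columns: {missing}")
    return cohort[_SEG_COLS].to_numpy(dtype=float)


def midseptal_r2star(t2star_ms) -> float:
    """Subject reference R2* (Hz): mean of segments 8 and 9.

    Accepts a 16-vector of segmental T2* (ms).
    """
    v = np.asarray(t2star_ms, dtype=float)
    if v.shape != (16,):
        raise ValueError("expected 16 segmental T2* values")
    idx = [k - 1 for k in MIDSEPTAL_SEGMENTS]
    if np.any(~np.isfinite(v[idx])):
        raise ValueError("mid-septal segments missing")
    return float(np.mean(t2star_to_r2star(v[idx])))


@dataclass(frozen=True)
class CorrectionFactorMap:
    """The 16 segmental correction factors dR2* (Hz)."""

    delta_r2star: np.ndarray  # (16,), Hz
    reference: str = "mean(seg8, seg9)"
    n_subjects: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.delta_r2star, dtype=float)
        if v.shape != (16,):
            raise ValueError("need exactly 16 correction factors")
        object.__setattr__(self, "delta_r2star", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_id": np.arange(1, 17),
                "aha_name": AHA_SEGMENT_NAMES,
                "delta_r2star_hz": self.delta_r2star,
            }
        )

    def save(self, csv_path) -> None:
        """Write the factor table plus a JSON sidecar with provenance."""
        path = Path(csv_path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {"reference": self.reference, "n_subjects": self.n_subjects},
                indent=2,
            )
        )

    @classmethod
    def load(cls, csv_path) -> "CorrectionFactorMap":
        path = Path(csv_path)
        df = pd.read_csv(path).sort_values("segment_id")
        meta = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            delta_r2star=df["delta_r2star_hz"].to_numpy(dtype=float),
            reference=meta.get("reference", "mean(seg8, seg9)"),
            n_subjects=int(meta.get("n_subjects", 0)),
        )


def estimate_correction_factors(cohort: pd.DataFrame) -> CorrectionFactorMap:
    """Estimate the segmental dR2* map from a healthy cohort table.

    Averages, over subjects, each segment's R2* deviation from the
    subject's mid-septal reference.  Rows with any missing or
    non-positive segmental value are excluded (count logged).
    """
    t2 = t2star_matrix(cohort)
    ok = np.all(np.isfinite(t2) & (t2 > 0), axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("excluding %d incomplete records", n_dropped)
    t2 = t2[ok]
    if len(t2) < 2:
        raise ValueError("need at least 2 complete records")
    r2 = 1000.0 / t2
    ms_ref = r2[:, [k - 1 for k in MIDSEPTAL_SEGMENTS]].mean(axis=1)
    delta = (r2 - ms_ref[:, None]).mean(axis=0)
    return CorrectionFactorMap(delta_r2star=delta, n_subjects=len(t2))


def factors_from_summary(summary: pd.DataFrame) -> CorrectionFactorMap:
    """Factors from a per-segment summary via the linearity identity.

    Averaging deviations commutes with averaging subjects, so the factor
    equals (segmental mean R2*) - (mean of the two mid-septal segmental
    means).  ``summary`` needs a ``mean_r2star`` column indexed by
    segment 1..16.
    """
    means = summary["mean_r2star"].to_numpy(dtype=float)
    if means.shape != (16,):
        raise ValueError("summary must cover exactly 16 segments")
    ref = means[[k - 1 for k in MIDSEPTAL_SEGMENTS]].mean()
    n = int(summary["n"].iloc[0]) if "n" in summary else 0
    return CorrectionFactorMap(delta_r2star=means - ref, n_subjects=n)


def apply_correction_values(t2star_ms, cfmap: CorrectionFactorMap) -> np.ndarray:
    """Corrected segmental T2* (ms): subtract dR2* in Hz, reconvert.

    Segments whose corrected rate would be non-positive are returned as
    NaN (uncorrectable) rather than a spurious negative relaxation time.
    Works on a 16-vector or an (n, 16) matrix.
    """
    t2 = np.asarray(t2star_ms, dtype=float)
    r2 = t2star_to_r2star(t2)
    corrected = r2 - cfmap.delta_r2star
    bad = corrected <= 0
    if bad.any():
        logger.warning("%d uncorrectable segment values (R2* <= 0)", int(bad.sum()))
    out = np.full_like(corrected, np.nan)
    out[~bad] = 1000.0 / corrected[~bad]
    return out


def apply_correction(
    cohort: pd.DataFrame, cfmap: CorrectionFactorMap
) -> pd.DataFrame:
    """Return a cohort table with corrected segmental T2* values."""
    out = cohort.copy()
    out[_SEG_COLS] = apply_correction_values(t2star_matrix(cohort), cfmap)
    return out


def apply_correction_record(
    record: SubjectSegmentalRecord, cfmap: CorrectionFactorMap
) -> np.ndarray:
    """Corrected 16-vector for one subject (NaN where uncorrectable)."""
    return apply_correction_values(record.t2star_ms, cfmap)


def compare_cohorts_segmental(
    a: pd.DataFrame, b: pd.DataFrame, bonferroni_m: int = 16
) -> pd.DataFrame:
    """Per-segment pooled two-sample t-tests between two cohort summaries.

    Both inputs are summary tables (columns ``n``, ``mean_r2star``,
    ``sd_r2star``; index segment 1..16).  Uses the pooled-variance
    (Student) t statistic with ``n_a + n_b - 2`` degrees of freedom and
    Bonferroni correction ``min(1, m * p)``.
    """
    for df_, name in ((a, "a"), (b, "b")):
        if np.any(df_["n"].to_numpy() < 2):
            raise ValueError(f"cohort {name} has a segment with n < 2")
    rows = []
    for seg in range(1, 17):
        ra, rb = a.loc[seg], b.loc[seg]
        t, p = stats.ttest_ind_from_stats(
            ra["mean_r2star"], ra["sd_r2star"], ra["n"],
            rb["mean_r2star"], rb["sd_r2star"], rb["n"],
            equal_var=True,
        )
        p_corr = min(1.0, bonferroni_m * p)
        rows.append(
            {
                "segment": seg,
                "aha_name": AHA_SEGMENT_NAMES[seg - 1],
                "t": float(t),
                "df": int(ra["n"] + rb["n"] - 2),
                "p": float(p),
                "p_bonferroni": float(p_corr),
                "significant_raw": bool(p < 0.05),
                "significant_bonferroni": bool(p_corr < 0.05),
            }
        )
    return pd.DataFrame(rows).set_index("segment")


def summarize_cohort(cohort: pd.DataFrame, label: str = "") -> pd.DataFrame:
    """Per-segment (n, mean R2*, SD R2*) summary of a cohort table."""
    r2 = 1000.0 / t2star_matrix(cohort)
    out = pd.DataFrame(
        {
            "aha_name": AHA_SEGMENT_NAMES,
            "n": np.sum(np.isfinite(r2), axis=0),
            "mean_r2star": np.nanmean(r2, axis=0),
            "sd_r2star": np.nanstd(r2, axis=0, ddof=1),
        },
        index=pd.RangeIndex(1, 17, name="segment"),
    )
    out.attrs["cohort"] = label
    return out
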