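import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from segt2star import (
    CVI_FACTORS,
    CVI_SUMMARY,
    HIPPO_SUMMARY,
    CohortDesign,
    CorrectionFactorMap,
    SubjectSegmentalRecord,
    apply_correction,
    apply_correction_values,
    compare_cohorts_segmental,
    estimate_correction_factors,
    factors_from_summary,
    generate_segmental_cohort,
    midseptal_r2star,
    t2star_matrix,
)


def _cohort_from_t2(t2: np.ndarray) -> pd.DataFrame:
    n = len(t2)
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "age_years": 40.0,
            "sex": "M",
        }
    )
    df[[f"t2s_seg{k:02d}" for k in range(1, 17)]] = t2
    return df


class TestMidseptalReference:
    def test_mean_of_segments_8_and_9(self):
        t2 = np.full(16, 30.0)
        t2[7] = 1000.0 / 28.5
        t2[8] = 1000.0 / 27.5
        assert midseptal_r2star(t2) == pytest.approx(28.0, abs=1e-12)

    def test_equal_septal_segments(self):
        t2 = np.full(16, 30.0)
        t2[7] = t2[8] = 1000.0 / 31.0
        assert midseptal_r2star(t2) == pytest.approx(31.0, abs=1e-12)

    def test_published_factor_consistency_sweep(self):
        """Mean-of-8/9 reference reproduces all 16 printed factors from
        the printed segmental means within the rounding budget."""
        cf = factors_from_summary(CVI_SUMMARY)
        assert np.all(np.abs(cf.delta_r2star - CVI_FACTORS.to_numpy()) <= 0.1)


class TestEstimateFactors:
    def test_two_subject_hand_arithmetic(self):
        t2 = np.full((2, 16), np.nan)
        t2[0] = 1000.0 / 28.0  # subject 1 mid-septum 28 Hz
        t2[1] = 1000.0 / 25.0
        t2[0, 0] = 1000.0 / 30.0  # segment 1: 30 and 26 Hz
        t2[1, 0] = 1000.0 / 26.0
        cf = estimate_correction_factors(_cohort_from_t2(t2))
        assert cf.delta_r2star[0] == pytest.approx(1.5, abs=1e-12)
        assert cf.n_subjects == 2

    def test_flat_subjects_give_zero_factors(self, rng):
        r2 = rng.uniform(25.0, 35.0, size=10)
        t2 = np.repeat((1000.0 / r2)[:, None], 16, axis=1)
        cf = estimate_correction_factors(_cohort_from_t2(t2))
        assert np.allclose(cf.delta_r2star, 0.0, atol=1e-12)

    def test_linearity_identity(self, default_cohort):
        """The averaged-deviation definition equals the difference of
        cohort means (linearity of the mean)."""
        cf = estimate_correction_factors(default_cohort)
        r2 = 1000.0 / t2star_matrix(default_cohort)
        direct = r2.mean(axis=0) - r2[:, [7, 8]].mean(axis=1).mean()
        assert np.allclose(cf.delta_r2star, direct, atol=1e-12)

    def test_reference_segments_antisymmetric(self, default_cohort):
        cf = estimate_correction_factors(default_cohort)
        assert cf.delta_r2star[7] + cf.delta_r2star[8] == pytest.approx(
            0.0, abs=1e-12
        )

    def test_incomplete_records_excluded(self, default_cohort):
        damaged = default_cohort.copy()
        damaged.loc[damaged.index[:3], "t2s_seg05"] = np.nan
        cf = estimate_correction_factors(damaged)
        assert cf.n_subjects == len(default_cohort) - 3
        with pytest.raises(ValueError):
            estimate_correction_factors(damaged.iloc[:3])


class TestApplyCorrection:
    def test_zero_factor_identity(self, default_cohort):
        cf = CorrectionFactorMap(np.zeros(16))
        corrected = apply_correction(default_cohort, cf)
        assert np.allclose(
            t2star_matrix(corrected), t2star_matrix(default_cohort)
        )

    def test_hand_arithmetic(self):
        out = apply_correction_values(
            np.full(16, 25.0), CorrectionFactorMap(np.full(16, 8.0))
        )
        assert np.allclose(out, 31.25)  # 40 Hz - 8 Hz -> 32 Hz

    @given(
        hst.floats(min_value=15.0, max_value=60.0),
        hst.floats(min_value=-5.0, max_value=10.0),
        hst.floats(min_value=0.01, max_value=5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_factor(self, t2, delta, step):
        """Larger factor, larger corrected T2* (and positive factor raises it)."""
        lo = apply_correction_values(
            np.full(16, t2), CorrectionFactorMap(np.full(16, delta))
        )[0]
        hi = apply_correction_values(
            np.full(16, t2), CorrectionFactorMap(np.full(16, delta + step))
        )[0]
        assert hi > lo
        if delta > 1e-6:  # beyond float rounding of the round trip
            assert lo > t2

    def test_uncorrectable_segment_flagged(self):
        t2 = np.full(16, 40.0)  # 25 Hz
        out = apply_correction_values(t2, CorrectionFactorMap(np.full(16, 30.0)))
        assert np.all(np.isnan(out))

    def test_self_correction_closure(self, default_cohort):
        """Correcting the estimation cohort equalises every corrected
        segmental mean R2* at the cohort mid-septal mean."""
        cf = estimate_correction_factors(default_cohort)
        r2 = 1000.0 / t2star_matrix(default_cohort)
        corrected_means = (r2 - cf.delta_r2star).mean(axis=0)
        ms = r2[:, [7, 8]].mean(axis=1).mean()
        assert np.allclose(corrected_means, ms, atol=1e-10)

    def test_held_out_range_reduction(self, default_cohort):
        """On independent cohorts from the same population the corrected
        segmental mean R2* values are mutually closer than the native ones."""
        cf = estimate_correction_factors(default_cohort)
        for seed in range(100, 110):
            held = generate_segmental_cohort(CohortDesign(seed=seed))
            native = (1000.0 / t2star_matrix(held)).mean(axis=0)
            corrected = native - cf.delta_r2star
            assert np.ptp(corrected) < np.ptp(native)


class TestCohortComparison:
    def test_reproduces_published_segment5(self):
        cmp = compare_cohorts_segmental(CVI_SUMMARY, HIPPO_SUMMARY)
        assert cmp.loc[5, "p"] == pytest.approx(0.0031, abs=5e-5)
        assert cmp.loc[5, "p_bonferroni"] == pytest.approx(0.0496, abs=8e-4)
        assert cmp.loc[5, "df"] == 70

    def test_identical_summaries_null(self):
        cmp = compare_cohorts_segmental(CVI_SUMMARY, CVI_SUMMARY)
        assert np.allclose(cmp["t"], 0.0)
        assert np.allclose(cmp["p"], 1.0)

    def test_significant_segment_counts(self):
        cmp = compare_cohorts_segmental(CVI_SUMMARY, HIPPO_SUMMARY)
        assert int(cmp["significant_raw"].sum()) == 8
        assert int(cmp["significant_bonferroni"].sum()) == 5

    def test_small_cohort_rejected(self):
        bad = CVI_SUMMARY.copy()
        bad["n"] = 1
        with pytest.raises(ValueError):
            compare_cohorts_segmental(bad, HIPPO_SUMMARY)


class TestRecordAndMapIO:
    def test_record_validation(self):
        with pytest.raises(ValueError):
            SubjectSegmentalRecord("S1", 30.0, "F", np.full(15, 30.0))
        with pytest.raises(ValueError):
            SubjectSegmentalRecord("S1", 30.0, "F", np.full(16, -1.0))

    def test_record_from_row_round_trip(self, default_cohort):
        rec = SubjectSegmentalRecord.from_row(default_cohort.iloc[0])
        assert rec.t2star_ms.shape == (16,)
        assert rec.wall_thickness_mm is not None
        assert set(rec.wall_thickness_mm) == set(range(7, 13))

    def test_map_save_load(self, tmp_path, default_cohort):
        cf = estimate_correction_factors(default_cohort)
        cf.save(tmp_path / "factors.csv")
        back = CorrectionFactorMap.load(tmp_path / "factors.csv")
        assert np.allclose(back.delta_r2star, cf.delta_r2star)
        assert back.n_subjects == cf.n_subjects
        assert back.reference == cf.reference
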