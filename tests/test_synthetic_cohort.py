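import numpy as np
import pandas as pd
import pytest

from segt2star import (
    CVI_SUMMARY,
    CohortDesign,
    EchoProtocol,
    PhantomGeometry,
    SegmentDistributionSpec,
    calibrate_age_slope,
    fit_pixelwise,
    generate_multiecho_phantom,
    generate_segmental_cohort,
    global_values,
    read_cohort_csv,
    segment_mean_t2star,
    t2star_matrix,
    write_cohort_csv,
    write_phantom_nifti,
)
from segt2star.cohort_stats import correlate
from segt2star.synthetic_cohort import SEGMENT_COLUMNS


class TestEchoProtocol:
    def test_default_echo_train(self, protocol):
        te = protocol.echo_times
        assert len(te) == 10
        assert te[0] == pytest.approx(2.02)
        assert np.allclose(np.diff(te), 2.26)
        assert protocol.echo_time(10) == pytest.approx(22.36)

    def test_bad_indices_and_parameters(self, protocol):
        with pytest.raises(ValueError):
            protocol.echo_time(0)
        with pytest.raises(ValueError):
            protocol.echo_time(11)
        with pytest.raises(ValueError):
            EchoProtocol(first_echo_time=-1.0)


class TestCohortGenerator:
    def test_determinism(self):
        a = generate_segmental_cohort(CohortDesign(seed=7))
        b = generate_segmental_cohort(CohortDesign(seed=7))
        c = generate_segmental_cohort(CohortDesign(seed=8))
        pd.testing.assert_frame_equal(a, b)
        assert not a[SEGMENT_COLUMNS].equals(c[SEGMENT_COLUMNS])

    def test_zero_sd_degenerate(self):
        spec = SegmentDistributionSpec(sd_r2star=np.zeros(16))
        cohort = generate_segmental_cohort(CohortDesign(seed=1), spec)
        t2 = t2star_matrix(cohort)
        assert np.allclose(t2, t2[0])  # every subject identical
        assert 1000.0 / t2[0, 4] == pytest.approx(36.3, abs=1e-12)

    def test_distributional_fidelity(self, large_cohort):
        """Sample segmental moments match the spec within 3 standard errors."""
        r2 = 1000.0 / t2star_matrix(large_cohort)
        n = len(r2)
        mu = CVI_SUMMARY["mean_r2star"].to_numpy()
        sd = CVI_SUMMARY["sd_r2star"].to_numpy()
        se_mean = sd / np.sqrt(n)
        se_sd = sd / np.sqrt(2 * n)
        # 16 simultaneous 3-SE checks: tolerate a single chance excursion
        assert np.sum(np.abs(r2.mean(axis=0) - mu) >= 3 * se_mean) <= 1
        assert np.sum(np.abs(r2.std(axis=0, ddof=1) - sd) >= 3 * se_sd) <= 1

    def test_design_balance(self, default_cohort):
        ages = default_cohort["age_years"]
        for lo, hi in CohortDesign().age_bins:
            sel = (ages >= lo) & (ages < hi)
            assert sel.sum() == 10
            assert (default_cohort.loc[sel, "sex"] == "M").sum() == 5

    def test_wall_thickness_sex_contrast(self, default_cohort):
        male = default_cohort["sex"] == "M"
        # published contrast ~1.6-1.8 mm; generous sanity band
        diff = (
            default_cohort.loc[male, "wt_seg09"].mean()
            - default_cohort.loc[~male, "wt_seg09"].mean()
        )
        assert 0.8 < diff < 3.0

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(n_subjects=0)
        with pytest.raises(ValueError):
            SegmentDistributionSpec(sd_r2star=np.full(16, -1.0))
        with pytest.raises(ValueError):
            SegmentDistributionSpec(mean_r2star=np.zeros(16))

    def test_age_slope_calibration(self):
        """Calibrated slope lands the n=50 sample r inside the r=-0.29
        Fisher sampling interval."""
        slope = calibrate_age_slope(-0.29)
        assert slope < 0
        cohort = generate_segmental_cohort(
            CohortDesign(age_effect_slope=slope, seed=3)
        )
        r, _, _ = correlate(
            cohort["age_years"], global_values(cohort), method="pearson"
        )
        z = np.arctanh(-0.29)
        half = 1.96 / np.sqrt(50 - 3)
        assert np.tanh(z - half) < r < np.tanh(z + half)

    def test_csv_round_trip(self, default_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort_csv(default_cohort, path)
        back = read_cohort_csv(path)
        assert np.allclose(
            back[SEGMENT_COLUMNS].to_numpy(),
            default_cohort[SEGMENT_COLUMNS].to_numpy(),
        )
        (tmp_path / "bad.csv").write_text("subject_id\nS1\n")
        with pytest.raises(ValueError):
            read_cohort_csv(tmp_path / "bad.csv")


class TestPhantom:
    def test_noiseless_recovery(self, protocol):
        """Log-linear fit of the noiseless phantom recovers the truth."""
        geom = PhantomGeometry(noise_sigma=0.0)
        t2seg = np.linspace(20.0, 45.0, 16)
        t2seg[4] = 25.0
        stack, masks, truth = generate_multiecho_phantom(
            geom, protocol, segment_t2star=t2seg, seed=0
        )
        assert stack.shape == (128, 128, 3, 10)
        for zi, level in enumerate(("basal", "mid", "apical")):
            t2map = fit_pixelwise(
                stack[:, :, zi, :], protocol.echo_times,
                mask=np.isfinite(truth[:, :, zi]),
            )
            myo = np.isfinite(truth[:, :, zi])
            assert np.allclose(t2map[myo], truth[:, :, zi][myo], rtol=1e-9)

    def test_rician_segment_mean_within_tolerance(self, protocol):
        """Rician noise at SNR 50: ROI-mean fitted T2* within 5% of truth."""
        geom = PhantomGeometry(
            pixel_spacing_mm=400.0 / 512.0,  # >=200 pixels per sector
            noise_sigma=1000.0 / 50.0,
            noise_model="rician",
        )
        stack, masks, _ = generate_multiecho_phantom(
            geom, protocol, segment_t2star=np.full(16, 35.0), seed=1
        )
        mask = masks.masks[8]
        assert mask.sum() >= 200
        t2map = fit_pixelwise(stack[:, :, 1, :], protocol.echo_times, mask=mask)
        mean, _ = segment_mean_t2star(t2map, mask)
        assert abs(mean - 35.0) / 35.0 < 0.05

    def test_phantom_determinism_and_validation(self, protocol):
        geom = PhantomGeometry(noise_sigma=5.0)
        a, _, _ = generate_multiecho_phantom(geom, protocol, seed=3)
        b, _, _ = generate_multiecho_phantom(geom, protocol, seed=3)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            generate_multiecho_phantom(
                geom, protocol, segment_t2star=np.full(16, -1.0)
            )
        with pytest.raises(ValueError):
            PhantomGeometry(endo_radius_mm=28.0, epi_radius_mm=30.0)

    def test_nifti_export(self, protocol, tmp_path):
        import nibabel as nib

        geom = PhantomGeometry()
        stack, masks, _ = generate_multiecho_phantom(geom, protocol, seed=0)
        write_phantom_nifti(stack, masks, protocol, tmp_path)
        img = nib.load(tmp_path / "phantom.nii.gz")
        assert img.shape == (128, 128, 3, 10)
        labels = np.asarray(nib.load(tmp_path / "segments.nii.gz").dataobj)
        assert set(np.unique(labels[:, :, 0])) == {0, 1, 2, 3, 4, 5, 6}
        assert (tmp_path / "echo_times.json").exists()
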