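"""Synthetic segmental cohorts and multi-echo phantom image stacks.

The generator emulates the study population behind the published
segmental reference values: 50 healthy adults, sex-balanced within five
age decades (20-69 years), imaged with a 10-echo black-blood
gradient-echo protocol (first echo 2.02 ms, spacing 2.26 ms, last echo
22.36 ms).  Each subject's segmental R2* values are drawn from
per-segment normal distributions (defaults: the published cohort
means/SDs), truncated to positive rates, then converted to T2*; an
optional linear age effect shifts a subject's T2* values uniformly
across segments.

The phantom generator renders idealised short-axis annuli with
segment-wise mono-exponential decay and Rician (magnitude) or Gaussian
noise, so the whole fitting chain can be exercised without any images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aha_model import PhantomGeometry, SegmentMaskSet, build_segment_masks
from .published import CVI_SUMMARY, SLICE_SEGMENTS, WALL_THICKNESS_BY_SEX

#: cohort-table column names for the 16 segmental T2* values (ms)
SEGMENT_COLUMNS: list[str] = [f"t2s_seg{k:02d}" for k in range(1, 17)]
#: optional wall-thickness columns (mm), mid-ventricular segments only
WALL_THICKNESS_COLUMNS: list[str] = [f"wt_seg{k:02d}" for k in range(7, 13)]


@dataclass(frozen=True)
class EchoProtocol:
    """Echo-time arithmetic of the multi-echo gradient-echo sequence."""

    first_echo_time: float = 2.02  # ms
    echo_spacing: float = 2.26  # ms
    n_echoes: int = 10

    def __post_init__(self) -> None:
        if self.first_echo_time <= 0 or self.echo_spacing <= 0:
            raise ValueError("echo times must be positive and increasing")
        if self.n_echoes < 1:
            raise ValueError("need at least one echo")

    def echo_time(self, i: int) -> float:
        """TE of echo ``i`` (1-based), ms."""
        if not 1 <= i <= self.n_echoes:
            raise ValueError(f"echo index {i} out of 1..{self.n_echoes}")
        return self.first_echo_time + (i - 1) * self.echo_spacing

    @property
    def echo_times(self) -> np.ndarray:
        return self.first_echo_time + self.echo_spacing * np.arange(self.n_echoes)


@dataclass(frozen=True)
class SegmentDistributionSpec:
    """Population parameters of the segmental R2* distributions (Hz).

    Defaults are the published healthy-cohort segmental means and SDs.
    Segments are drawn independently; ``subject_sd_hz`` > 0 adds a shared
    per-subject random intercept on top (a crude inter-segment
    correlation model).
    """

    mean_r2star: np.ndarray = field(
        default_factory=lambda: CVI_SUMMARY["mean_r2star"].to_numpy()
    )
    sd_r2star: np.ndarray = field(
        default_factory=lambda: CVI_SUMMARY["sd_r2star"].to_numpy()
    )
    subject_sd_hz: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.mean_r2star, dtype=float)
        s = np.asarray(self.sd_r2star, dtype=float)
        if m.shape != (16,) or s.shape != (16,):
            raise ValueError("need exactly 16 segmental means and SDs")
        if np.any(m <= 0):
            raise ValueError("segmental mean R2* must be positive")
        if np.any(s < 0) or self.subject_sd_hz < 0:
            raise ValueError("SDs must be non-negative")
        object.__setattr__(self, "mean_r2star", m)
        object.__setattr__(self, "sd_r2star", s)


_DEFAULT_BINS = ((20, 30), (30, 40), (40, 50), (50, 60), (60, 70))


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design of the healthy cohort.

    ``age_effect_slope`` is in ms of global T2* per year, applied as an
    additive shift (centred on the design's mid-range age) to every
    segment's T2*; the default 0 turns the effect off.
    """

    n_subjects: int = 50
    sex_balance: float = 0.5
    age_bins: tuple[tuple[int, int], ...] = _DEFAULT_BINS
    age_effect_slope: float = 0.0
    include_wall_thickness: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not 0.0 <= self.sex_balance <= 1.0:
            raise ValueError("sex_balance must be in [0, 1]")
        for lo, hi in self.age_bins:
            if hi <= lo:
                raise ValueError("age bins must satisfy lo < hi")

    @property
    def age_midrange(self) -> float:
        return 0.5 * (self.age_bins[0][0] + self.age_bins[-1][1])


def calibrate_age_slope(
    target_r: float,
    spec: SegmentDistributionSpec | None = None,
    design: CohortDesign | None = None,
) -> float:
    """Slope (ms/year) giving a population age-T2* Pearson ``target_r``.

    Uses the delta-method SD of the global T2* under the spec,
    ``var(1000/X) ~ (1000 sd / mu^2)^2`` per segment averaged over 16
    independent segments, and the uniform-age SD over the design's full
    range.  Negative ``target_r`` yields a negative slope.
    """
    if not -1.0 < target_r < 1.0:
        raise ValueError("target_r must be in (-1, 1)")
    spec = spec or SegmentDistributionSpec()
    design = design or CohortDesign()
    var_seg = (1000.0 * spec.sd_r2star / spec.mean_r2star**2) ** 2
    sigma_g = np.sqrt(var_seg.sum() / 16.0**2)
    span = design.age_bins[-1][1] - design.age_bins[0][0]
    sigma_age = span / np.sqrt(12.0)
    return float(target_r * sigma_g / (sigma_age * np.sqrt(1.0 - target_r**2)))


def _truncated_normal(rng: np.random.Generator, mean, sd, size) -> np.ndarray:
    """Normal draws resampled until positive (R2* is a physical rate)."""
    out = rng.normal(mean, sd, size=size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(np.broadcast_to(mean, size)[bad], np.broadcast_to(sd, size)[bad])
        bad = out <= 0
    return out


def generate_segmental_cohort(
    design: CohortDesign | None = None,
    spec: SegmentDistributionSpec | None = None,
) -> pd.DataFrame:
    """Draw a cohort table of per-subject segmental T2* values.

    Returns one row per subject with columns ``subject_id, age_years,
    sex, t2s_seg01..t2s_seg16`` (ms) and, when enabled,
    ``wt_seg07..wt_seg12`` (mm) with the published male-female thickness
    contrast.  Subjects are assigned to age bins round-robin and sexes
    alternate within each bin, so the default design is exactly balanced.
    Draws are reproducible for a fixed ``design.seed``.
    """
    design = design or CohortDesign()
    spec = spec or SegmentDistributionSpec()
    rng = np.random.default_rng(design.seed)
    n = design.n_subjects

    bins = list(design.age_bins)
    bin_idx = np.arange(n) % len(bins)
    # alternate sexes within each bin -> exact balance per bin
    sex = np.empty(n, dtype=object)
    for b in range(len(bins)):
        members = np.flatnonzero(bin_idx == b)
        n_male = int(round(len(members) * design.sex_balance))
        pattern = ["M", "F"] * len(members)
        males = [m for i, m in enumerate(members) if pattern[i] == "M"][:n_male]
        sex[members] = "F"
        sex[males] = "M"
    ages = np.array(
        [rng.uniform(bins[b][0], bins[b][1]) for b in bin_idx]
    )

    r2 = _truncated_normal(rng, spec.mean_r2star, spec.sd_r2star, (n, 16))
    if spec.subject_sd_hz > 0:
        shift = rng.normal(0.0, spec.subject_sd_hz, size=(n, 1))
        r2 = np.clip(r2 + shift, 1e-6, None)
    t2 = 1000.0 / r2
    if design.age_effect_slope != 0.0:
        t2 = t2 + design.age_effect_slope * (ages - design.age_midrange)[:, None]
        if np.any(t2 <= 0):
            raise ValueError("age effect drove T2* non-positive; reduce slope")

    out = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "age_years": ages,
            "sex": sex,
        }
    )
    out[SEGMENT_COLUMNS] = t2
    if design.include_wall_thickness:
        male = sex == "M"
        for k in range(7, 13):
            mm, ms_, fm, fs = WALL_THICKNESS_BY_SEX[k]
            wt = np.where(
                male,
                rng.normal(mm, ms_, size=n),
                rng.normal(fm, fs, size=n),
            )
            out[f"wt_seg{k:02d}"] = np.clip(wt, 1.0, None)
    return out


def generate_multiecho_phantom(
    geometry: PhantomGeometry | None = None,
    protocol: EchoProtocol | None = None,
    segment_t2star=None,
    seed: int = 0,
):
    """Render a noisy multi-echo short-axis stack with known ground truth.

    Each of the three slice levels (basal, mid, apical) is an annulus
    sectored into its AHA segments; every pixel of segment ``k`` decays
    as ``S0 exp(-TE / T2*_k)``.  Noise is Rician
    (``sqrt((S+n1)^2 + n2^2)``, the magnitude-image model) or additive
    Gaussian.  Blood pool and background sit at the black-blood
    (near-zero) signal level.

    Returns ``(stack, mask_set, truth)`` where ``stack`` has shape
    ``(nx, ny, 3, n_echoes)`` and ``truth`` is the noiseless pixel T2*
    map (ms, NaN outside the myocardium).
    """
    geometry = geometry or PhantomGeometry()
    protocol = protocol or EchoProtocol()
    if segment_t2star is None:
        segment_t2star = 1000.0 / CVI_SUMMARY["mean_r2star"].to_numpy()
    t2seg = np.asarray(segment_t2star, dtype=float)
    if t2seg.shape != (16,):
        raise ValueError("need exactly 16 segmental T2* values")
    if np.any(t2seg <= 0):
        raise ValueError("segment T2* must be positive")

    mask_set = build_segment_masks(geometry)
    rng = np.random.default_rng(seed)
    te = protocol.echo_times
    levels = list(SLICE_SEGMENTS)
    nx = ny = geometry.grid_size
    stack = np.empty((nx, ny, len(levels), protocol.n_echoes))
    truth = np.full((nx, ny, len(levels)), np.nan)

    for zi, level in enumerate(levels):
        t2map = np.full((nx, ny), np.nan)
        for seg in SLICE_SEGMENTS[level]:
            t2map[mask_set.masks[seg]] = t2seg[seg - 1]
        truth[:, :, zi] = t2map
        myo = np.isfinite(t2map)
        for ei, t in enumerate(te):
            clean = np.where(
                myo,
                geometry.s0 * np.exp(-t / np.where(myo, t2map, 1.0)),
                geometry.blood_pool_signal,
            )
            if geometry.noise_sigma > 0:
                if geometry.noise_model == "rician":
                    n1 = rng.normal(0.0, geometry.noise_sigma, clean.shape)
                    n2 = rng.normal(0.0, geometry.noise_sigma, clean.shape)
                    clean = np.hypot(clean + n1, n2)
                else:
                    clean = clean + rng.normal(
                        0.0, geometry.noise_sigma, clean.shape
                    )
            stack[:, :, zi, ei] = clean
    return stack, mask_set, truth


# ---------------------------------------------------------------------------
# on-disk formats


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", "age_years", "sex") if c not in df]
    missing += [c for c in SEGMENT_COLUMNS if c not in df]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    return df


def write_phantom_nifti(
    stack: np.ndarray,
    mask_set: SegmentMaskSet,
    protocol: EchoProtocol,
    out_dir,
    pixel_spacing_mm: float = 400.0 / 256.0,
) -> None:
    """Write the phantom as NIfTI-1 volumes plus an echo-time sidecar.

    ``phantom.nii.gz`` is the 4-D (x, y, slice, echo) stack,
    ``segments.nii.gz`` the integer-labelled masks (1-16), and
    ``echo_times.json`` lists the TEs in ms.
    """
    import nibabel as nib  # local: IO only

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([pixel_spacing_mm, pixel_spacing_mm, 8.0, 1.0])
    nib.save(nib.Nifti1Image(stack.astype(np.float32), affine), out / "phantom.nii.gz")
    labels = np.stack(
        [mask_set.labeled_slice(lvl) for lvl in SLICE_SEGMENTS], axis=-1
    )
    nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), out / "segments.nii.gz")
    (out / "echo_times.json").write_text(
        json.dumps({"echo_times_ms": protocol.echo_times.tolist()}, indent=2)
    )
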