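# Methods

## Signal model and fitting

A myocardial voxel in a multi-echo gradient-echo acquisition decays as
`S(TE) = S0 exp(−TE/T2*)`; with echo times in ms the relaxation rate is
`R2* (Hz) = 1000/T2* (ms)`. Two fitters are provided:

- **log-linear** (default): unweighted least squares of `ln S` on TE.
  Transparent and fast; on noiseless data it is exact to machine
  precision. Zero or negative signals cannot enter the log fit and are
  dropped.
- **nonlinear**: Levenberg–Marquardt on the exponential itself,
  initialised from the log-linear estimate. Preferred at low SNR
  because log-transforming reweights the noise toward the late echoes;
  Monte-Carlo at S0=500, σ=2, T2\*=20 ms shows a median bias well
  under 1%.

A fit with fewer than 3 usable echoes, or with a non-decaying slope,
is flagged invalid and excluded from segment averages instead of
reporting an unbounded T2\*. Truncation is off by default — over the
default 10-echo train (2.02–22.36 ms) a healthy T2\* > 20 ms keeps
every echo far above any realistic noise floor — but a noise-floor
rule (drop trailing echoes below `2σ`) is available for short-T2\*
work.

Averaging domains are deliberately asymmetric, matching the measurement
convention: segment values are arithmetic means of per-pixel **T2\***
estimates (not a fit of the mean signal), and the global value is the
arithmetic mean of the 16 segmental **T2\*** values; the correction
arithmetic, by contrast, lives entirely in **R2\***. Because `1/x` is
convex, the mean of segmental T2\* exceeds the reciprocal of the mean
R2\* (Jensen), which is why a cohort can show a native global mean of
~34 ms while its segmental mean rates average ~30 Hz.

## Segment model

The 16 AHA segments are idealised annular sectors on three short-axis
slices: 6×60° basal, 6×60° mid, 4×90° apical, numbered
counterclockwise from the anterior RV-insertion angle (apical sectors
shifted −45° so the anterior sector straddles the anterior direction).
The annulus is eroded radially by the contour offset (default 2 mm) on
both the endocardial and epicardial side before sectoring, mimicking
ROIs drawn inside the contours to avoid blood pool and epicardial fat.
The true apex (segment 17) is excluded. Masks are exact partitions of
the eroded annulus; manual ROI placement on real images is not
replicated.

## Correction-factor map

For subject *j* the mid-septal reference rate `R2*_ms,j` is the mean of
segments 8 and 9 — the definition that reproduces every published
factor from the published segmental means within rounding (e.g.
36.3 − (28.5+27.5)/2 = 8.3 vs the printed 8.31). The factor for
segment *k* is the cohort-averaged deviation
`ΔR2*_k = mean_j(R2*_kj − R2*_ms,j)`, which by linearity equals the
difference of cohort means; both computations are asserted to agree to
1e−12. The factors for segments 8 and 9 are antisymmetric (they sum to
zero) by construction, and applying a map to the cohort that produced
it equalises all corrected segmental mean rates at the cohort
mid-septal mean exactly.

Application subtracts `ΔR2*_k` in Hz and reconverts: `T2*_corr =
1000/(1000/T2* − ΔR2*_k)`. A measurement whose corrected rate would be
non-positive is flagged uncorrectable (NaN) and excluded from
downstream averages rather than silently clamped.

Cohort-vs-cohort comparison from summary tables uses the
pooled-variance (Student) two-sample t-test with `n_a + n_b − 2`
degrees of freedom and Bonferroni multiplier 16 — the combination that
reproduces the published p-values (0.0031 → ×16 = 0.0496) where the
Welch test does not. Note that the published corrected column is 16×
the *rounded* raw p.

## Synthetic cohort generator

The generator emulates the reference study population; its defaults are
the study conditions, not free dials:

| parameter | default | meaning |
|---|---|---|
| n_subjects | 50 | cohort size |
| sex_balance | 0.5 | exact alternation within each age bin |
| age_bins | five decades 20–69 | equal counts per bin, ages uniform in-bin |
| mean/sd R2\* per segment | published cohort column (Hz) | segmental population parameters |
| subject_sd_hz | 0 | optional shared per-subject rate intercept |
| age_effect_slope | 0 (off) | ms global T2\* per year, additive in T2\* |
| wall thickness | published sex-specific mean ± SD (mm), segments 7–12 | reproduces the ~1.6–1.8 mm male–female contrast |
| echo protocol | 2.02 ms first echo, 2.26 ms spacing, 10 echoes | last echo 22.36 ms |

Segmental rates are drawn independently per segment as
`Normal(mean_k, sd_k)` resampled to stay positive, then converted to
T2\*. Independence is a modelling choice — no inter-segment covariance
is published — and it suffices to recover the published global means;
a shared subject-level intercept is available where correlated
segments matter. The weak negative age effect is an additive
subject-level T2\* shift whose slope is calibrated by the delta method
so the population age–T2\* Pearson correlation hits a requested target
(−0.29 gives ≈ −0.031 ms/year over ages 20–69); the default leaves it
off so null analyses are genuinely null.

The phantom renders these segments as annular sectors with
per-segment decay, black-blood (zero-mean) pool and background, and
Rician noise by default (`sqrt((S+n1)² + n2²)`, the magnitude-image
model) with Gaussian available for analytic checks. It carries its
noiseless ground truth, so fitting-chain errors are measurable: at
SNR 50 the segment-mean fitted T2\* is within ~1% of truth.

What the generator does **not** emulate: realistic anatomy and wall
thinning, motion/breathing artifacts, the actual spatial structure of
susceptibility fields (segmental fluctuation is imposed through the
distribution spec, not modelled from field maps), inter-segment
correlation of real hearts, and scanner/sequence-specific bias. Tests
passing on this material show the estimators and the pipeline are
correct under the stated statistical model — not that the published
factors transfer to other scanners or sequences.

## Reproducibility statistics

Paired repeat measurements are tested with a Shapiro–Wilk gate at
α=0.05 on the differences: paired t when normality is not rejected,
Wilcoxon signed-rank otherwise (constant differences are degenerate,
p=1). Bland–Altman limits use the plain `bias ± 1.96·SD` multiplier —
not a t-quantile — because that reproduces the published limits from
the published mean ± SD (1.96 × 0.88 ≈ 1.73). The ICC is fixed to
two-way random effects, absolute agreement, single measures (ICC(2,1)),
the conservative choice for test–retest when the published variant is
unstated; values from other forms are not comparable. Repeat "scans"
in the synthetic pathway add independent Gaussian measurement noise
per context (defaults 3.0 / 1.8 / 2.2 ms for inter-study,
intra-operator, inter-operator), chosen to sit in the range implied by
published per-segment difference SDs; the published ICC values
themselves depend on unavailable raw images and are not targeted.

## Covariate analyses

Group comparisons and correlations use the same normality gate
(Student t vs Mann–Whitney; Pearson vs Spearman). The multivariable
analysis is ordinary least squares of segmental (or global) T2\* on
age, sex, and wall thickness, without interactions; wall thickness
enters only for the mid-ventricular segments where it is measured.
P-values are Bonferroni-corrected across the responses tested in one
call. Under the null generator roughly 85–90% of replicates show no
corrected-significant predictor — with 6 responses × 3 predictors a
~14% familywise false-alarm rate at the 0.05/6 threshold is expected
arithmetic, not a defect.

## Numerical choices and known limits

- Simulation sizes: population-recovery checks use n=5000 subjects
  (segmental-mean standard errors ≈ 0.1 Hz); property sweeps use 10–100
  seeds; the phantom grid is 128² (512-matrix spacing where ≥200 pixels
  per sector are needed). These sizes make every statistical tolerance
  in the tests comfortably attainable.
- **Heavy tail of the reciprocal.** Dividing by a normal rate is
  heavy-tailed: `E[1/X]` under a positive-truncated normal is dominated
  by rare near-zero draws (formally the integral diverges at 0), and
  the corrected apical/basal lateral segments (corrected mean ≈ 28 Hz,
  SD up to 8.5 Hz) feel this. Two consequences are documented rather
  than hidden: (i) at n=50 a single small corrected rate can inflate a
  stratum mean/SD visibly; (ii) at n=5000 the simulated corrected
  means sit ≈ 0.5–0.7 ms above the second-order approximation
  `(1000/μ)(1+σ²/μ²)`, because the higher even moments of 1/X
  contribute at CV ≈ 0.3. Range-reduction properties are therefore
  asserted in the R2\* domain, where correction is an exact constant
  shift.
- Uncorrectable segments (corrected rate ≤ 0) are excluded per
  segment, not per subject; a subject's global corrected mean uses the
  remaining segments.
- The published factor map is sequence-, scanner- and software-
  specific; nothing here validates transfer to patients with iron
  overload, pediatric populations, or other field strengths.
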