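# segt2star

Segmental myocardial T2\*/R2\* relaxometry with septum-referenced
correction factors, for people building or validating a segmental
approach to cardiac iron quantification by MRI.

Global myocardial T2\* (the average over the whole left ventricle) is
the established marker of cardiac iron overload, but iron deposits
heterogeneously, and a per-segment reading is more sensitive. The
obstacle is that healthy myocardium already shows systematic
segment-wise T2\* fluctuations from susceptibility and geometric
artifacts (diaphragm, pulmonary veins, heart–lung interface), so raw
segmental values need an artifact correction before they can be
compared against a single normal cutoff.

## The model

Multi-echo gradient-echo signal decays mono-exponentially,

```
S(TE) = S0 · exp(−TE / T2*),        R2* (Hz) = 1000 / T2* (ms)
```

Per-pixel fits are averaged arithmetically inside each of the 16 AHA
segments (6 basal, 6 mid, 4 apical sectors on three short-axis slices),
and the global value is the arithmetic mean of the 16 segmental T2\*
values. The mid-ventricular septum (segments 8–9) is conventionally
free of susceptibility artifacts, so each segment's correction factor
is its average deviation from it, in the rate domain:

```
ΔR2*_k = (1/N) Σ_j ( R2*_kj − R2*_ms,j )
```

over a healthy cohort of N subjects, where `R2*_ms,j` is subject *j*'s
mean rate in segments 8–9. Correcting a measurement subtracts `ΔR2*_k`
in Hz and reconverts to ms; a positive factor raises the corrected
T2\*. The package carries the published factor map from a 50-subject
black-blood cohort (and the earlier 22-subject white-blood comparator)
as reference tables, and estimates fresh maps from any cohort table.

## Layout

- `src/segt2star/` — the library: `synthetic_cohort` (cohort and
  phantom generators), `relaxometry` (decay fitting, conversions,
  segment/global averaging), `aha_model` (segment masks, bull's-eye),
  `correction` (factor estimation/application, cohort comparison),
  `agreement` (paired tests, Bland–Altman, ICC), `cohort_stats`
  (normative tables, correlations, multivariable model).
- `analysis/01…05_*.py` — numbered drivers reproducing the full
  analysis on synthetic data; each writes its tables under `results/`.
- `docs/methods.md` — model, assumptions, parameter choices, limits.

## Worked example

```python
import numpy as np
from segt2star import (CohortDesign, generate_segmental_cohort,
                       estimate_correction_factors, apply_correction,
                       global_values)

cohort = generate_segmental_cohort(CohortDesign(seed=0))   # 50 subjects
cf = estimate_correction_factors(cohort)
print(np.round(cf.delta_r2star[3:5], 2))    # basal inferior / inferolateral
corrected = apply_correction(cohort, cf)
print(round(global_values(cohort).mean(), 2),
      round(global_values(corrected).mean(), 2))
```

prints

```
[8.8  7.15]
34.43 38.34
```

— the basal inferior and inferolateral factors are large and positive
(these segments sit over the diaphragm and read systematically fast
rates), and correction moves the cohort's mean global T2\* up from
34.43 ms past the mid-septal reference of ≈35.7 ms; at n=50 the
corrected mean overshoots a little because dividing by small corrected
rates is heavy-tailed (see `docs/methods.md`). Running the numbered drivers
in order regenerates the full set of tables; for instance
`analysis/03_correction_factors.py` reports that the published n=50
vs n=22 segmental comparison yields 8 significant segments raw and 5
after Bonferroni, and `analysis/05_reproducibility.py` prints global
inter-study limits of agreement of about ±1.4 ms with ICC > 0.9 under
the default repeat-measurement noise.

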