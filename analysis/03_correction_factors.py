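#!/usr/bin/env python
"""Estimate the segmental correction-factor map and compare cohorts.

Estimates the mid-septum-referenced segmental dR2* map from the
synthetic cohort (results/cohort.csv, regenerated if absent), writes it
next to the published factors, and runs the per-segment pooled t-test
comparison between the published commercial-software cohort (n=50) and
the published HIPPO cohort (n=22) with Bonferroni correction.

Outputs: results/correction_factors.csv (+ .json sidecar),
results/cohort_comparison.csv.
"""

from pathlib import Path

import pandas as pd

from segt2star import (
    CVI_FACTORS,
    CVI_SUMMARY,
    HIPPO_SUMMARY,
    CohortDesign,
    calibrate_age_slope,
    compare_cohorts_segmental,
    estimate_correction_factors,
    generate_segmental_cohort,
    read_cohort_csv,
)

OUT = Path("results")


def main() -> None:
    path = OUT / "cohort.csv"
    if path.exists():
        cohort = read_cohort_csv(path)
    else:
        cohort = generate_segmental_cohort(
            CohortDesign(age_effect_slope=calibrate_age_slope(-0.29), seed=0)
        )
    cf = estimate_correction_factors(cohort)
    OUT.mkdir(exist_ok=True)
    cf.save(OUT / "correction_factors.csv")  # CSV + JSON provenance sidecar
    table = cf.to_frame()
    table["published_delta_r2star_hz"] = CVI_FACTORS.to_numpy()
    table.to_csv(OUT / "correction_factors.csv", index=False)

    print("estimated vs published segmental dR2* (Hz):")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    dev = (table["delta_r2star_hz"] - table["published_delta_r2star_hz"]).abs()
    print(f"\nmax |estimated - published| = {dev.max():.2f} Hz "
          f"(sampling error at n={cf.n_subjects})")

    cmp = compare_cohorts_segmental(CVI_SUMMARY, HIPPO_SUMMARY)
    cmp.to_csv(OUT / "cohort_comparison.csv")
    n_raw = int(cmp["significant_raw"].sum())
    n_corr = int(cmp["significant_bonferroni"].sum())
    print(f"\ncohort comparison (published summaries, pooled t, df=70): "
          f"{n_raw} segments significant raw, {n_corr} after Bonferroni")
    print(f"wrote {OUT / 'correction_factors.csv'}, {OUT / 'cohort_comparison.csv'}")


if __name__ == "__main__":
    main()
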