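#!/usr/bin/env python
"""Fit the multi-echo phantom and check segment-level recovery.

Renders a three-slice short-axis phantom whose 16 AHA segments decay
with the published cohort-mean T2* values, adds Rician noise at SNR 50,
fits every myocardial pixel log-linearly over the 10-echo train, and
averages per segment.  Writes the per-segment comparison with the
ground truth to results/phantom_segment_means.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from segt2star import (
    CVI_SUMMARY,
    EchoProtocol,
    PhantomGeometry,
    fit_pixelwise,
    generate_multiecho_phantom,
    segment_mean_t2star,
)
from segt2star.published import SLICE_SEGMENTS

OUT = Path("results")
SEED = 0


def main() -> None:
    protocol = EchoProtocol()
    geometry = PhantomGeometry(noise_sigma=1000.0 / 50.0, noise_model="rician")
    truth_t2 = 1000.0 / CVI_SUMMARY["mean_r2star"].to_numpy()
    stack, masks, _ = generate_multiecho_phantom(
        geometry, protocol, segment_t2star=truth_t2, seed=SEED
    )

    rows = []
    for zi, (level, segs) in enumerate(SLICE_SEGMENTS.items()):
        t2map = fit_pixelwise(
            stack[:, :, zi, :], protocol.echo_times,
            mask=masks.labeled_slice(level) > 0,
        )
        for seg in segs:
            mean, sd = segment_mean_t2star(t2map, masks.masks[seg])
            rows.append(
                {
                    "segment": seg,
                    "slice": level,
                    "n_pixels": int(masks.masks[seg].sum()),
                    "true_t2star_ms": truth_t2[seg - 1],
                    "fitted_mean_ms": mean,
                    "fitted_sd_ms": sd,
                    "rel_error": mean / truth_t2[seg - 1] - 1.0,
                }
            )
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "phantom_segment_means.csv", index=False)

    worst = np.abs(table["rel_error"]).max()
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"\nworst segment-mean relative error at SNR 50: {worst:.3%}")
    print(f"wrote {OUT / 'phantom_segment_means.csv'}")


if __name__ == "__main__":
    main()
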