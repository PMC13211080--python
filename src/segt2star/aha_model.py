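"""AHA 16-segment model on three short-axis slices.

The left ventricle is partitioned into 6 basal (segments 1-6), 6
mid-ventricular (7-12) and 4 apical (13-16) sectors of an annulus.
Sectors are numbered counterclockwise from the anterior right-ventricular
insertion point, in a view with the RV on the image left.  Before
sectoring, the annulus is eroded radially by the contour offset on both
the endocardial and epicardial side, mimicking ROIs drawn a couple of
millimetres inside the contours to avoid blood pool and epicardial fat.
The true apex (segment 17) is not part of this model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .published import AHA_SEGMENT_NAMES, SLICE_SEGMENTS

#: sectors per slice level and angular width (degrees)
_SECTORS = {"basal": (6, 60.0), "mid": (6, 60.0), "apical": (4, 90.0)}


@dataclass(frozen=True)
class PhantomGeometry:
    """Idealised short-axis geometry of the LV myocardium.

    Defaults follow a 400 mm field of view on a 256 matrix
    (1.5625 mm pixels) downsampled to a 128 grid, with a mid-ventricular
    annulus of 22-32 mm radius and the conventional 2 mm contour offset.
    """

    grid_size: int = 128
    pixel_spacing_mm: float = 400.0 / 256.0
    center: tuple[float, float] | None = None  # (row, col); grid centre if None
    endo_radius_mm: float = 22.0
    epi_radius_mm: float = 32.0
    reference_angle_deg: float = 90.0  # anterior RV insertion
    slice_level: str = "mid"
    contour_offset_mm: float = 2.0
    s0: float = 1000.0
    noise_sigma: float = 0.0
    noise_model: str = "rician"  # or "gaussian"
    blood_pool_signal: float = 0.0  # black blood: nulled pool

    def __post_init__(self) -> None:
        if not (self.epi_radius_mm > self.endo_radius_mm > 0):
            raise ValueError("need epi_radius > endo_radius > 0")
        if self.contour_offset_mm < 0:
            raise ValueError("contour offset must be >= 0")
        inner = self.endo_radius_mm + self.contour_offset_mm
        outer = self.epi_radius_mm - self.contour_offset_mm
        if outer <= inner:
            raise ValueError("eroded annulus is empty")
        if self.slice_level not in _SECTORS:
            raise ValueError(f"unknown slice level {self.slice_level!r}")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def center_px(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        c = (self.grid_size - 1) / 2.0
        return (c, c)


def _polar_grid(geom: PhantomGeometry):
    """Radius (mm) and angle (deg, ccw, RV-left display convention)."""
    rows, cols = np.mgrid[0 : geom.grid_size, 0 : geom.grid_size]
    cy, cx = geom.center_px
    x = (cols - cx) * geom.pixel_spacing_mm
    y = (cy - rows) * geom.pixel_spacing_mm  # image up == +y
    radius = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x))
    return radius, theta


@dataclass(frozen=True)
class SegmentMaskSet:
    """Pixel masks of the 16 AHA segments over the three slice levels."""

    masks: dict[int, np.ndarray]  # segment id -> 2-D bool mask on its slice
    grid_size: int
    level_of: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.level_of:
            lut = {s: lvl for lvl, segs in SLICE_SEGMENTS.items() for s in segs}
            object.__setattr__(
                self, "level_of", {s: lut[s] for s in self.masks}
            )

    def segments(self) -> list[int]:
        return sorted(self.masks)

    def labeled_slice(self, level: str) -> np.ndarray:
        """Integer-labelled mask image (0 background, labels 1-16)."""
        out = np.zeros((self.grid_size, self.grid_size), dtype=np.int16)
        for seg in SLICE_SEGMENTS[level]:
            if seg in self.masks:
                out[self.masks[seg]] = seg
        return out


def build_segment_masks(
    geom: PhantomGeometry, levels: tuple[str, ...] = ("basal", "mid", "apical")
) -> SegmentMaskSet:
    """Sector the eroded annulus into AHA segments for the given levels.

    Basal and mid slices get six 60° sectors, the apical slice four 90°
    sectors; numbering runs counterclockwise from the anterior RV
    insertion (``geom.reference_angle_deg``).  Apical sectors are shifted
    by -45° so the anterior sector straddles the anterior direction.
    """
    radius, theta = _polar_grid(geom)
    inner = geom.endo_radius_mm + geom.contour_offset_mm
    outer = geom.epi_radius_mm - geom.contour_offset_mm
    annulus = (radius >= inner) & (radius <= outer)
    if not annulus.any():
        raise ValueError("eroded annulus contains no pixels")

    masks: dict[int, np.ndarray] = {}
    for level in levels:
        n_sec, width = _SECTORS[level]
        start = geom.reference_angle_deg - (45.0 if level == "apical" else 0.0)
        sector = np.floor(((theta - start) % 360.0) / width).astype(int)
        base = SLICE_SEGMENTS[level][0]
        for j in range(n_sec):
            m = annulus & (sector == j)
            if not m.any():
                raise ValueError(f"empty sector {base + j} at {level} level")
            masks[base + j] = m
    return SegmentMaskSet(masks=masks, grid_size=geom.grid_size)


def bullseye_table(values) -> pd.DataFrame:
    """Order a 16-vector of segmental values into the AHA report layout.

    Returns one row per segment labelled ``"1. basal anterior"`` ...
    ``"16. apical lateral"`` with slice level and value columns.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (16,):
        raise ValueError("expected exactly 16 segmental values")
    lut = {s: lvl for lvl, segs in SLICE_SEGMENTS.items() for s in segs}
    return pd.DataFrame(
        {
            "segment": np.arange(1, 17),
            "label": [
                f"{i + 1}. {AHA_SEGMENT_NAMES[i]}" for i in range(16)
            ],
            "slice": [lut[i + 1] for i in range(16)],
            "value": v,
        }
    )


def plot_bullseye(values, ax=None, cmap: str = "viridis", fmt: str = "{:.1f}"):
    """Polar bull's-eye display of 16 segmental values (3 rings).

    Outer ring basal, middle ring mid-ventricular, inner ring apical.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt  # local: plotting is optional

    v = np.asarray(values, dtype=float)
    if v.shape != (16,):
        raise ValueError("expected exactly 16 segmental values")
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    norm = plt.Normalize(v.min(), v.max())
    cm = plt.get_cmap(cmap)
    rings = {"basal": (2.0, 3.0), "mid": (1.0, 2.0), "apical": (0.0, 1.0)}
    for level, (r0, r1) in rings.items():
        segs = SLICE_SEGMENTS[level]
        width = 2 * np.pi / len(segs)
        offset = np.pi / 2 - (np.pi / 4 if level == "apical" else 0.0)
        for j, seg in enumerate(segs):
            th = offset + j * width
            ax.bar(
                th + width / 2, r1 - r0, width=width, bottom=r0,
                color=cm(norm(v[seg - 1])), edgecolor="w",
            )
            ax.text(
                th + width / 2, (r0 + r1) / 2, fmt.format(v[seg - 1]),
                ha="center", va="center", fontsize=7,
            )
    ax.set_yticks([])
    ax.set_xticks([])
    return ax
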