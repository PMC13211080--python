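"""Mono-exponential T2*/R2* relaxometry.

The gradient-echo signal of a voxel with effective transverse relaxation
time T2* decays as ``S(TE) = S0 * exp(-TE / T2*)``.  With TE in ms,
``R2* (Hz) = 1000 / T2* (ms)``.  Segment values are the arithmetic mean
of the per-pixel T2* estimates inside the segment ROI, and the global
value is the arithmetic mean of the 16 segmental T2* values — both
computed in the T2* (ms) domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize


def t2star_to_r2star(t2star_ms):
    """Convert T2* (ms) to R2* (Hz) via ``R2* = 1000 / T2*``.

    Accepts scalars or arrays; all values must be positive.
    """
    t2 = np.asarray(t2star_ms, dtype=float)
    if np.any(t2 <= 0):
        raise ValueError("T2* must be positive (ms)")
    out = 1000.0 / t2
    return float(out) if np.isscalar(t2star_ms) else out


def r2star_to_t2star(r2star_hz):
    """Convert R2* (Hz) to T2* (ms); the inverse of :func:`t2star_to_r2star`."""
    r2 = np.asarray(r2star_hz, dtype=float)
    if np.any(r2 <= 0):
        raise ValueError("R2* must be positive (Hz)")
    out = 1000.0 / r2
    return float(out) if np.isscalar(r2star_hz) else out


@dataclass(frozen=True)
class DecaySample:
    """Signal intensities of one pixel or ROI across the echo train."""

    echo_times: np.ndarray  # ms, strictly increasing
    signals: np.ndarray  # arbitrary units, >= 0

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if te.ndim != 1 or s.shape != te.shape:
            raise ValueError("echo_times and signals must be 1-D of equal length")
        if len(te) < 3:
            raise ValueError("need at least 3 echoes")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if np.any(s < 0):
            raise ValueError("signals must be non-negative")
        object.__setattr__(self, "echo_times", te)
        object.__setattr__(self, "signals", s)


@dataclass(frozen=True)
class FitResult:
    """Result of a mono-exponential decay fit.

    ``valid`` is False when the fit is degenerate (non-decaying signal or
    fewer than 3 usable echoes); such pixels are excluded from segment
    averages.
    """

    t2star: float  # ms (inf when invalid)
    s0: float
    r2star: float  # Hz (0 when invalid)
    goodness: float  # coefficient of determination, clipped to [0, 1]
    n_echoes_used: int
    valid: bool = True

    @staticmethod
    def invalid(n_echoes_used: int = 0) -> "FitResult":
        return FitResult(np.inf, np.nan, 0.0, 0.0, n_echoes_used, valid=False)


def _usable(sample: DecaySample, truncation, noise_sigma: float):
    """Apply the truncation rule, returning (te, s) of the usable echoes."""
    te, s = sample.echo_times, sample.signals
    if truncation == "noise_floor":
        # drop trailing echoes once the signal falls below twice the noise SD
        below = s < 2.0 * noise_sigma
        keep = len(s)
        while keep > 0 and below[keep - 1]:
            keep -= 1
        te, s = te[:keep], s[:keep]
    # log-linear fit cannot use zero signals
    pos = s > 0
    return te[pos], s[pos]


def fit_monoexponential(
    sample: DecaySample,
    method: Literal["loglinear", "nonlinear"] = "loglinear",
    truncation: Literal["none", "noise_floor"] = "none",
    noise_sigma: float = 0.0,
) -> FitResult:
    """Fit ``S(TE) = S0 exp(-TE/T2*)`` to one decay sample.

    ``loglinear`` is an unweighted least-squares line through
    ``ln S`` vs TE; ``nonlinear`` refines it with Levenberg–Marquardt on
    the exponential model.  ``noise_floor`` truncation drops trailing
    echoes with signal below ``2 * noise_sigma``.
    """
    te, s = _usable(sample, truncation, noise_sigma)
    if len(s) < 3:
        return FitResult.invalid(len(s))

    slope, intercept = np.polyfit(te, np.log(s), 1)
    if slope >= 0:  # non-decaying signal: T2* unbounded
        return FitResult.invalid(len(s))
    t2, s0 = -1.0 / slope, float(np.exp(intercept))

    if method == "nonlinear":
        try:
            (s0, t2), _ = optimize.curve_fit(
                lambda x, a, b: a * np.exp(-x / b), te, s, p0=(s0, t2), maxfev=2000
            )
        except RuntimeError:
            return FitResult.invalid(len(s))
        if t2 <= 0:
            return FitResult.invalid(len(s))

    pred = s0 * np.exp(-te / t2)
    ss_res = float(np.sum((s - pred) ** 2))
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return FitResult(
        t2star=float(t2),
        s0=float(s0),
        r2star=1000.0 / float(t2),
        goodness=float(np.clip(r2, 0.0, 1.0)),
        n_echoes_used=len(s),
    )


def fit_pixelwise(
    stack: np.ndarray,
    echo_times: np.ndarray,
    mask: np.ndarray | None = None,
    method: Literal["loglinear", "nonlinear"] = "loglinear",
) -> np.ndarray:
    """Per-pixel T2* map (ms) from an echo-last image stack.

    ``stack`` has shape ``spatial + (n_echoes,)``.  Pixels with a
    degenerate fit (non-positive or non-decaying signal) are NaN.  The
    log-linear path is vectorised; the nonlinear path loops over pixels.
    """
    te = np.asarray(echo_times, dtype=float)
    spatial = stack.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    out = np.full(spatial, np.nan)
    sig = stack[mask]  # (npix, necho)
    ok = np.all(sig > 0, axis=1)
    t2 = np.full(len(sig), np.nan)
    if ok.any():
        logs = np.log(sig[ok])
        design = np.vstack([te, np.ones_like(te)]).T
        coef, *_ = np.linalg.lstsq(design, logs.T, rcond=None)
        slope = coef[0]
        decaying = slope < 0
        vals = np.full(ok.sum(), np.nan)
        vals[decaying] = -1.0 / slope[decaying]
        t2[ok] = vals
    if method == "nonlinear":
        idx = np.flatnonzero(ok)
        for i in idx:
            if not np.isfinite(t2[i]):
                continue
            res = fit_monoexponential(DecaySample(te, sig[i]), method="nonlinear")
            t2[i] = res.t2star if res.valid else np.nan
    out[mask] = t2
    return out


def segment_mean_t2star(pixel_t2star_map: np.ndarray, mask: np.ndarray):
    """Arithmetic mean ± sample SD of valid pixel T2* values inside a mask.

    This is an average of per-pixel estimates, not a fit of the mean
    signal.  NaN/inf pixels (invalid fits) are excluded.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty segment mask")
    vals = np.asarray(pixel_t2star_map)[mask]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no valid pixels in segment")
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return float(np.mean(vals)), sd


def global_t2star(segmental_t2star_ms) -> float:
    """Unweighted arithmetic mean of the 16 segmental T2* values (ms)."""
    v = np.asarray(segmental_t2star_ms, dtype=float)
    if v.shape != (16,):
        raise ValueError("expected exactly 16 segmental values")
    if not np.all(np.isfinite(v)):
        raise ValueError("missing segmental value")
    return float(v.mean())
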