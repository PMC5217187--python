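"""Leakage-corrected cerebral blood volume by trapezoidal integration.

When the blood-brain barrier is disrupted, gadolinium extravasates and the
measured dR2*(t) in enhancing voxels is contaminated by T1 (signal up,
apparent concentration down) and residual T2/T2* effects.  The standard
reference-curve linear model expresses each voxel's curve in terms of the
average curve of non-enhancing tissue, dR2bar(t):

    dR2*_voxel(t)  ≈  K1 · dR2bar(t)  -  K2 · ∫_0^t dR2bar(t') dt'

K1 captures the voxel's blood-volume scaling; K2 the leakage rate.  The
corrected curve adds the leakage term back:

    corrected(t) = measured(t) + K2 · ∫_0^t dR2bar(t') dt'

CBV is then the trapezoidal integral of the corrected curve between the bolus
entrance and exit, optionally with the bounds re-located on each voxel's own
concentration curve.  Negative integrals are retained; clipping them would
bias downstream agreement statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .bolus_detection import BolusTiming, refine_voxel_bounds
from .concentration import ConcentrationSeries
from .errors import FitError, MaskError

__all__ = [
    "LeakageModel",
    "CbvMaps",
    "nonenhancing_mask",
    "build_reference_curve",
    "fit_leakage",
    "corrected_curves",
    "integrate_cbv",
]

# Tail deviation threshold: 2 baseline-SD plus a floor of 2% of the voxel's
# peak |dR2*| so that noiseless non-leaky voxels (SD = 0) are not excluded.
# The tail is the last quarter of the series, past the recirculation bump.
_TAIL_SD_FACTOR = 2.0
_TAIL_PEAK_FRACTION = 0.02


@dataclass
class LeakageModel:
    """Reference curve, its running integral, and per-voxel K1/K2 maps."""

    reference_curve: np.ndarray  # (t,), mean dR2* of non-enhancing tissue
    cumulative_reference: np.ndarray  # (t,), running trapezoidal integral
    k1_map: np.ndarray | None = None  # (z, y, x)
    k2_map: np.ndarray | None = None  # (z, y, x), per unit time

    @property
    def fitted(self) -> bool:
        return self.k1_map is not None and self.k2_map is not None


@dataclass
class CbvMaps:
    """Uncorrected/corrected CBV, the leakage coefficients, and (later) rCBV."""

    cbv_uncorrected: np.ndarray
    cbv_corrected: np.ndarray
    k1_map: np.ndarray | None
    k2_map: np.ndarray | None
    rcbv: np.ndarray | None = None
    wm_mean_cbv: float | None = None


def nonenhancing_mask(
    conc: ConcentrationSeries,
    tumor_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Non-enhancing tissue: brain minus tumor minus leaky-tail voxels.

    A voxel is 'leaky-tailed' when the mean of its late dR2* tail (the last
    quarter of the series, after first pass and recirculation have cleared)
    deviates from the (zero) baseline by more than 2 baseline-SD plus 2% of
    its peak |dR2*|.
    """
    mask = conc.mask.copy()
    if tumor_mask is not None:
        mask &= ~tumor_mask
    if not mask.any():
        raise MaskError("non-enhancing mask is empty after tumor exclusion")
    curves = conc.delta_r2s[:, mask]  # (t, n)
    base = curves[conc.timing.baseline_slice]
    base_sd = base.std(axis=0, ddof=1)
    tail_start = conc.n_frames - max(4, conc.n_frames // 4)
    tail_start = max(tail_start, conc.timing.exit + 1)
    tail_mean = np.abs(curves[tail_start:].mean(axis=0))
    peak = np.abs(curves).max(axis=0)
    ok = tail_mean <= _TAIL_SD_FACTOR * base_sd + _TAIL_PEAK_FRACTION * peak
    out = np.zeros_like(mask)
    out[mask] = ok
    if not out.any():
        # Degenerate fallback: keep the least-deviating half.
        order = np.argsort(tail_mean)
        keep = np.zeros(tail_mean.size, dtype=bool)
        keep[order[: max(1, tail_mean.size // 2)]] = True
        out[mask] = keep
    return out


def build_reference_curve(
    conc: ConcentrationSeries,
    nonenhancing: np.ndarray,
) -> LeakageModel:
    """Average dR2*(t) over non-enhancing voxels plus its running integral."""
    if not np.asarray(nonenhancing, bool).any():
        raise MaskError("non-enhancing mask is empty")
    reference = conc.curves(np.asarray(nonenhancing, bool)).mean(axis=1)
    cumulative = cumulative_trapezoid(reference, dx=conc.frame_spacing, initial=0.0)
    return LeakageModel(reference_curve=reference, cumulative_reference=cumulative)


def fit_leakage(
    conc: ConcentrationSeries,
    model: LeakageModel,
) -> LeakageModel:
    """Per-voxel OLS of the measured curve on [reference, -cumulative reference].

    The fit window runs from the bolus entrance to the last frame: leakage
    expresses in the post-bolus tail, while pre-bolus frames carry none.
    """
    ref = model.reference_curve
    cum = model.cumulative_reference
    if not np.any(np.abs(ref) > 0):
        raise FitError("reference curve is identically zero")
    t0 = conc.timing.entrance
    design = np.column_stack([ref[t0:], -cum[t0:]])  # (T, 2)
    if np.linalg.matrix_rank(design) < 2:
        raise FitError("degenerate design matrix for the leakage fit")
    y = conc.curves()[t0:]  # (T, n)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    k1 = np.full(conc.spatial_shape, np.nan)
    k2 = np.full(conc.spatial_shape, np.nan)
    k1[conc.mask] = coef[0]
    k2[conc.mask] = coef[1]
    return LeakageModel(
        reference_curve=ref,
        cumulative_reference=cum,
        k1_map=k1,
        k2_map=k2,
    )


def corrected_curves(conc: ConcentrationSeries, model: LeakageModel) -> np.ndarray:
    """Leakage-corrected 4D dR2* array: measured + K2 * cumulative reference."""
    if not model.fitted:
        raise FitError("leakage model has no fitted K1/K2 maps")
    k2 = np.where(np.isfinite(model.k2_map), model.k2_map, 0.0)
    return conc.delta_r2s + k2[None] * model.cumulative_reference[:, None, None, None]


def _trapz_between(curve: np.ndarray, lo: int, hi: int, dx: float) -> float:
    return float(np.trapezoid(curve[lo : hi + 1], dx=dx))


def integrate_cbv(
    conc: ConcentrationSeries,
    model: LeakageModel | None,
    timing: BolusTiming,
    per_voxel_bounds: bool = False,
    search_radius: int = 3,
) -> CbvMaps:
    """CBV maps by trapezoidal integration between the bolus entrance and exit.

    With ``per_voxel_bounds`` the bounds are re-located on each voxel's
    concentration curve within ``search_radius`` frames of the global bounds
    (falling back to the global bounds for flat or noise-only curves).  The
    corrected map integrates the leakage-corrected curves; when no fitted
    model is given the corrected map equals the uncorrected one.
    """
    dx = conc.frame_spacing
    shape = conc.spatial_shape
    uncorr = np.full(shape, np.nan)
    corr = np.full(shape, np.nan)
    if model is not None and model.fitted:
        corrected = corrected_curves(conc, model)
        k1, k2 = model.k1_map, model.k2_map
    else:
        corrected = conc.delta_r2s
        k1 = k2 = None
    voxels = np.argwhere(conc.mask)
    e0, x0 = timing.entrance, timing.exit
    for z, y, x in voxels:
        raw = conc.delta_r2s[:, z, y, x]
        if per_voxel_bounds:
            lo, hi = refine_voxel_bounds(raw, timing, search_radius)
            if hi <= lo:
                lo, hi = e0, x0
        else:
            lo, hi = e0, x0
        uncorr[z, y, x] = _trapz_between(raw, lo, hi, dx)
        corr[z, y, x] = _trapz_between(corrected[:, z, y, x], lo, hi, dx)
    return CbvMaps(
        cbv_uncorrected=uncorr,
        cbv_corrected=corr,
        k1_map=k1,
        k2_map=k2,
    )
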