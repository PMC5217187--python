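"""Wavelet-based bolus delineation on the brain-average signal-time curve.

The first pass of a gadolinium bolus appears as a transient signal drop on
T2*-weighted dynamic images.  The trough of that drop is located as the
strongest minimum ridge of a Ricker (Mexican-hat) continuous wavelet
transform: extrema of the CWT coefficients are found at each scale and linked
across adjacent scales, and ridges that persist over enough scales are kept.
The bolus entrance and exit are the local maxima of the (lightly smoothed)
curve nearest the trough on either side; the pre-bolus baseline window runs
from the first kept frame up to the frame before the entrance.

The whole procedure is invariant to positive rescaling of the curve and to
adding a constant offset (the Ricker wavelet has zero mean).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy import ndimage

from .errors import (
    BoundaryError,
    InsufficientFramesError,
    MaskError,
    NoBolusError,
    ScaleError,
)
from .io_volumes import DscSeries

__all__ = [
    "BolusTiming",
    "WaveletExtrema",
    "discard_saturation_frames",
    "derive_brain_mask",
    "mean_brain_curve",
    "cwt_extrema",
    "locate_bolus",
    "refine_voxel_bounds",
    "detect_bolus",
    "DEFAULT_SCALES",
]

DEFAULT_SCALES = np.arange(1, 13)
DEFAULT_MIN_RIDGE_LENGTH = 3
DEFAULT_LINK_TOLERANCE = 2
DEFAULT_SATURATION_FRAMES = 3
DEFAULT_SEARCH_RADIUS = 3
# Extrema weaker than this fraction of the curve's range are numerical noise
# (a straight line has zero Ricker response away from the edges).
_RIDGE_STRENGTH_FLOOR = 1e-6


@dataclass(frozen=True)
class BolusTiming:
    """Bolus landmarks, indexed on the post-discard time axis.

    ``baseline_window`` is an inclusive frame range ending before the
    entrance; ``entrance < trough < exit`` always holds.
    """

    n_discarded: int
    baseline_window: tuple[int, int]
    entrance: int
    trough: int
    exit: int

    def __post_init__(self) -> None:
        if not (self.entrance < self.trough < self.exit):
            raise NoBolusError(
                f"invalid ordering: entrance={self.entrance}, "
                f"trough={self.trough}, exit={self.exit}"
            )
        if self.baseline_window[1] >= self.entrance:
            raise NoBolusError("baseline window must end before the bolus entrance")

    @property
    def baseline_slice(self) -> slice:
        return slice(self.baseline_window[0], self.baseline_window[1] + 1)


@dataclass
class Ridge:
    """One chain of same-polarity CWT extrema linked across adjacent scales."""

    polarity: int  # +1 maxima ridge, -1 minima ridge
    scale_indices: list[int]
    positions: list[int]
    strengths: list[float]  # |coefficient| at each linked extremum

    @property
    def length(self) -> int:
        return len(self.positions)

    @property
    def strength(self) -> float:
        return float(sum(self.strengths))

    @property
    def base_position(self) -> int:
        """Position at the smallest linked scale (best time localization)."""
        i = int(np.argmin(self.scale_indices))
        return self.positions[i]


@dataclass
class WaveletExtrema:
    """Per-scale CWT extrema and the retained cross-scale ridges."""

    scales: np.ndarray
    coefficients: np.ndarray  # (n_scales, n_frames)
    maxima: list[np.ndarray]  # per-scale extremum positions
    minima: list[np.ndarray]
    ridges: list[Ridge]  # retained (length >= min ridge length)

    @property
    def minimum_ridges(self) -> list[Ridge]:
        return [r for r in self.ridges if r.polarity < 0]

    @property
    def maximum_ridges(self) -> list[Ridge]:
        return [r for r in self.ridges if r.polarity > 0]


def discard_saturation_frames(
    series: DscSeries, n: int = DEFAULT_SATURATION_FRAMES
) -> DscSeries:
    """Drop the first ``n`` frames, which are distorted by T1 saturation."""
    if n < 0:
        raise InsufficientFramesError("n must be >= 0")
    if n >= series.n_frames - 8:
        raise InsufficientFramesError(
            f"discarding {n} of {series.n_frames} frames leaves fewer than 8"
        )
    if n == 0:
        return series
    return replace(series, signal=series.signal[n:])


def derive_brain_mask(series: DscSeries) -> np.ndarray:
    """Brain mask from an Otsu threshold on the temporal-mean volume.

    Keeps the largest connected component above the threshold.
    """
    from skimage.filters import threshold_otsu

    mean_vol = series.signal.mean(axis=0)
    thr = threshold_otsu(mean_vol)
    fg = mean_vol > thr
    if not fg.any():
        raise MaskError("no voxels above the Otsu threshold")
    lab, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def mean_brain_curve(series: DscSeries) -> np.ndarray:
    """Average signal-time curve over the brain mask (derived if absent)."""
    mask = series.brain_mask
    if mask is None:
        mask = derive_brain_mask(series)
    if not mask.any():
        raise MaskError("brain mask is empty")
    return series.signal[:, mask].mean(axis=1)


def _smooth(curve: np.ndarray, width: int = 3) -> np.ndarray:
    """Moving average with edge-value padding (keeps length)."""
    pad = width // 2
    padded = np.pad(np.asarray(curve, float), pad, mode="edge")
    kernel = np.ones(width) / width
    return np.convolve(padded, kernel, mode="valid")


def _per_scale_extrema(row: np.ndarray, margin: int, floor: float):
    """Interior local maxima/minima of one coefficient row above a strength floor."""
    n = row.size
    interior = np.arange(1, n - 1)
    is_max = (row[interior] >= row[interior - 1]) & (row[interior] > row[interior + 1])
    is_min = (row[interior] <= row[interior - 1]) & (row[interior] < row[interior + 1])
    maxima = interior[is_max]
    minima = interior[is_min]
    keep = lambda idx: idx[
        (idx >= margin) & (idx <= n - 1 - margin) & (np.abs(row[idx]) > floor)
    ]
    return keep(maxima), keep(minima)


def _link_ridges(
    positions_per_scale: list[np.ndarray],
    coefficients: np.ndarray,
    polarity: int,
    tolerance: int,
) -> list[Ridge]:
    """Greedy nearest-neighbour linking of extrema across adjacent scales."""
    active: list[Ridge] = []
    done: list[Ridge] = []
    for s, pos in enumerate(positions_per_scale):
        unmatched = set(int(p) for p in pos)
        still_active = []
        for ridge in active:
            last = ridge.positions[-1]
            candidates = [p for p in unmatched if abs(p - last) <= tolerance]
            if candidates:
                p = min(candidates, key=lambda q: (abs(q - last), q))
                unmatched.discard(p)
                ridge.scale_indices.append(s)
                ridge.positions.append(p)
                ridge.strengths.append(abs(float(coefficients[s, p])))
                still_active.append(ridge)
            else:
                done.append(ridge)
        for p in sorted(unmatched):
            still_active.append(
                Ridge(
                    polarity=polarity,
                    scale_indices=[s],
                    positions=[p],
                    strengths=[abs(float(coefficients[s, p]))],
                )
            )
        active = still_active
    done.extend(active)
    return done


def cwt_extrema(
    curve: np.ndarray,
    scales: np.ndarray | None = None,
    min_ridge_length: int = DEFAULT_MIN_RIDGE_LENGTH,
    link_tolerance: int = DEFAULT_LINK_TOLERANCE,
) -> WaveletExtrema:
    """Ricker-wavelet CWT extrema with cross-scale ridge linking.

    Ridges persisting over at least ``min_ridge_length`` adjacent scales are
    retained; weaker single-scale extrema are treated as noise.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size < 8:
        raise ScaleError(f"curve too short ({curve.size} frames)")
    if scales is None:
        scales = DEFAULT_SCALES
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0) or np.any(np.diff(scales) <= 0):
        raise ScaleError("scales must be positive and strictly ascending")
    if curve.size < 2 * scales.max():
        raise ScaleError(
            f"curve length {curve.size} shorter than the support of "
            f"scale {scales.max()}"
        )
    coefficients, _ = pywt.cwt(curve, scales, "mexh")
    span = float(curve.max() - curve.min())
    floor = _RIDGE_STRENGTH_FLOOR * span if span > 0 else np.inf
    maxima, minima = [], []
    for s_idx, s in enumerate(scales):
        margin = max(1, int(round(s)))
        mx, mn = _per_scale_extrema(coefficients[s_idx], margin, floor)
        maxima.append(mx)
        minima.append(mn)
    ridges = _link_ridges(maxima, coefficients, +1, link_tolerance)
    ridges += _link_ridges(minima, coefficients, -1, link_tolerance)
    retained = [r for r in ridges if r.length >= min_ridge_length]
    return WaveletExtrema(
        scales=scales,
        coefficients=coefficients,
        maxima=maxima,
        minima=minima,
        ridges=retained,
    )


def _nearest_local_max(
    sm: np.ndarray, start: int, step: int, tol: float
) -> int | None:
    """First index from ``start`` in direction ``step`` that is a local max.

    Flat shoulders count: a point is accepted when it is not exceeded (beyond
    ``tol``) by either neighbour, so the end of a flat pre-bolus plateau is
    found even without a strict maximum.
    """
    n = sm.size
    i = start
    while 0 < i < n - 1:
        if sm[i] >= sm[i - 1] - tol and sm[i] >= sm[i + 1] - tol:
            return i
        i += step
    return None


def locate_bolus(
    extrema: WaveletExtrema,
    curve: np.ndarray,
    n_discarded: int = 0,
    smooth_width: int = 3,
) -> BolusTiming:
    """Locate trough, entrance and exit from retained minimum ridges.

    The trough is the base position of the strongest minimum ridge (largest
    summed |coefficient|; ties broken toward the earlier position).  Entrance
    and exit are the nearest local maxima of the smoothed curve before and
    after the trough.
    """
    curve = np.asarray(curve, dtype=float)
    min_ridges = extrema.minimum_ridges
    # A signal drop is a *minimum* of the curve; its CWT response with the
    # (positive-centred) Ricker wavelet is a negative trough, so require the
    # ridge coefficients to be negative at the base scale.
    min_ridges = [
        r
        for r in min_ridges
        if extrema.coefficients[r.scale_indices[0], r.positions[0]] < 0
    ]
    if not min_ridges:
        raise NoBolusError("no minimum ridge retained: no bolus detected")
    best = min(min_ridges, key=lambda r: (-r.strength, r.base_position))
    trough = best.base_position
    # The ridge localizes the dip to within a sample or two; snap to the
    # actual minimum of the smoothed curve in a +-2 frame window.
    sm0 = _smooth(curve, smooth_width)
    lo = max(0, trough - 2)
    hi = min(curve.size, trough + 3)
    trough = lo + int(np.argmin(sm0[lo:hi]))
    if trough <= 0 or trough >= curve.size - 1:
        raise BoundaryError(f"bolus trough at frame {trough} touches the series edge")
    sm = _smooth(curve, smooth_width)
    span = float(curve.max() - curve.min())
    # Flatness tolerance: numerical floor plus 3x a robust noise estimate
    # (median absolute first difference), so plateau noise cannot drag the
    # entrance/exit search past the bolus shoulder.
    d = np.diff(sm)
    sigma = 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)
    tol = (1e-9 * span if span > 0 else 0.0) + 3.0 * sigma
    entrance = _nearest_local_max(sm, trough - 1, -1, tol)
    exit_ = _nearest_local_max(sm, trough + 1, +1, tol)
    if entrance is None or entrance < 1:
        raise NoBolusError("no pre-bolus plateau found before the trough")
    if exit_ is None:
        raise NoBolusError("no post-bolus recovery found after the trough")
    return BolusTiming(
        n_discarded=n_discarded,
        baseline_window=(0, entrance - 1),
        entrance=int(entrance),
        trough=int(trough),
        exit=int(exit_),
    )


def refine_voxel_bounds(
    voxel_curve: np.ndarray,
    global_timing: BolusTiming,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
) -> tuple[int, int]:
    """Per-voxel entrance/exit by local search on the concentration curve.

    On a concentration curve the bolus is a peak, so the integration bounds
    are the concentration minima hugging it.  Each bound is searched within
    ``search_radius`` frames of the global bound; entrance takes the latest
    index achieving the local minimum and exit the earliest, so the bounds
    hug the first pass.  Curves without bolus structure (flat or noise-only)
    fall back to the global bounds.
    """
    c = np.asarray(voxel_curve, dtype=float)
    n = c.size
    e0, x0 = global_timing.entrance, global_timing.exit

    base = c[global_timing.baseline_slice]
    base_sd = float(base.std(ddof=1)) if base.size > 1 else 0.0
    peak_window = c[e0 : x0 + 1]
    if peak_window.size == 0 or not np.isfinite(c).all():
        return e0, x0
    # Require a real first-pass peak above baseline fluctuation.
    if peak_window.max() - base.mean() <= 3.0 * base_sd:
        return e0, x0

    def window(center: int) -> np.ndarray:
        lo = max(0, center - search_radius)
        hi = min(n - 1, center + search_radius)
        return np.arange(lo, hi + 1)

    w_e = window(e0)
    vals_e = c[w_e]
    min_e = vals_e.min()
    near_e = w_e[np.isclose(vals_e, min_e, rtol=1e-9, atol=1e-12 + 1e-9 * abs(min_e))]
    entrance = int(near_e.max())  # latest frame at the minimum: start of the rise

    w_x = window(x0)
    vals_x = c[w_x]
    min_x = vals_x.min()
    near_x = w_x[np.isclose(vals_x, min_x, rtol=1e-9, atol=1e-12 + 1e-9 * abs(min_x))]
    exit_ = int(near_x.min())  # earliest frame at the minimum: end of the decay

    if exit_ <= entrance:
        return e0, x0
    return entrance, exit_


def detect_bolus(
    series: DscSeries,
    saturation_frames: int = DEFAULT_SATURATION_FRAMES,
    scales: np.ndarray | None = None,
    min_ridge_length: int = DEFAULT_MIN_RIDGE_LENGTH,
) -> tuple[DscSeries, BolusTiming]:
    """Run the full bolus-delineation chain; returns the trimmed series + timing."""
    trimmed = discard_saturation_frames(series, saturation_frames)
    if trimmed.brain_mask is None:
        trimmed = replace(trimmed, brain_mask=derive_brain_mask(trimmed))
    curve = mean_brain_curve(trimmed)
    extrema = cwt_extrema(curve, scales=scales, min_ridge_length=min_ridge_length)
    timing = locate_bolus(extrema, curve, n_discarded=saturation_frames)
    return trimmed, timing
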