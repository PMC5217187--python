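"""rCBV normalization, ROI summaries, and agreement statistics.

rCBV divides every voxel's corrected CBV by the mean corrected CBV of the
normal-appearing white-matter ROI, so the WM ROI has mean rCBV exactly 1 and
all units cancel.  ROI summaries are the mean and the 95th percentile
(linear interpolation between closest ranks; the hot-spot statistic is
sensitive to the rule, so it is recorded).  Agreement between measurement
methods is quantified with Bland-Altman bias and limits of agreement
(bias ± 2·SD of the paired differences, sample SD) and the one-way
random-effects intraclass correlation

    ICC(1,1) = (MSB - MSW) / (MSB + (k-1)·MSW)

from the one-way ANOVA mean squares of an n-subjects × k-raters table; the
average-measure form ICC(1,k) = (MSB - MSW)/MSB is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    CompletenessError,
    DegenerateDataError,
    NormalizationError,
    PairingError,
    StatsError,
)
from .leakage_cbv import CbvMaps
from .wm_selection import WmRoi

__all__ = [
    "RoiStats",
    "AgreementResult",
    "normalize_rcbv",
    "roi_stats",
    "bland_altman",
    "icc_oneway",
]

PERCENTILE_INTERPOLATION = "linear"  # between closest ranks


@dataclass
class RoiStats:
    roi_name: str
    mean_rcbv: float
    p95_rcbv: float
    n_voxels: int
    percentile_rule: str = PERCENTILE_INTERPOLATION


@dataclass
class AgreementResult:
    """Bland-Altman bias/limits and/or an intraclass correlation."""

    bias: float | None = None
    loa_low: float | None = None
    loa_high: float | None = None
    sd_diff: float | None = None
    icc: float | None = None
    n_pairs: int = 0


def normalize_rcbv(cbv: CbvMaps, wm: WmRoi) -> CbvMaps:
    """Fill ``cbv.rcbv`` = corrected CBV / mean corrected CBV over the WM ROI."""
    if wm.n_voxels < 1 or not wm.mask.any():
        raise NormalizationError("WM ROI is empty")
    wm_vals = cbv.cbv_corrected[wm.mask]
    wm_vals = wm_vals[np.isfinite(wm_vals)]
    if wm_vals.size == 0:
        raise NormalizationError("no finite CBV inside the WM ROI")
    wm_mean = float(wm_vals.mean())
    if wm_mean <= 0:
        raise NormalizationError(f"non-positive WM mean CBV ({wm_mean:g})")
    cbv.rcbv = cbv.cbv_corrected / wm_mean
    cbv.wm_mean_cbv = wm_mean
    return cbv


def roi_stats(rcbv: np.ndarray, roi: np.ndarray, name: str) -> RoiStats:
    """Mean and 95th percentile of a map over the finite voxels of an ROI."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise StatsError(f"ROI '{name}' is empty")
    vals = np.asarray(rcbv)[roi]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise StatsError(f"ROI '{name}' has no finite voxels")
    return RoiStats(
        roi_name=name,
        mean_rcbv=float(vals.mean()),
        p95_rcbv=float(np.percentile(vals, 95, method=PERCENTILE_INTERPOLATION)),
        n_voxels=int(vals.size),
    )


def bland_altman(a: np.ndarray, b: np.ndarray) -> AgreementResult:
    """Bias and limits of agreement (bias ± 2·SD of differences, sample SD)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise PairingError(f"paired lengths differ: {a.size} vs {b.size}")
    if a.size < 2:
        raise PairingError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        bias=bias,
        loa_low=bias - 2.0 * sd,
        loa_high=bias + 2.0 * sd,
        sd_diff=sd,
        n_pairs=int(a.size),
    )


def icc_oneway(ratings: np.ndarray, average_measure: bool = False) -> AgreementResult:
    """One-way random-effects intraclass correlation from an n × k table.

    Single-measure ICC(1,1) by default; set ``average_measure`` for ICC(1,k).
    Raises on missing cells and on zero total variance (any returned value
    would be arbitrary).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise CompletenessError("ratings must be an n>=2 by k>=2 table")
    if not np.isfinite(x).all():
        raise CompletenessError("ratings table has missing cells")
    n, k = x.shape
    row_means = x.mean(axis=1)
    grand = x.mean()
    ssb = k * float(((row_means - grand) ** 2).sum())
    ssw = float(((x - row_means[:, None]) ** 2).sum())
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msb == 0 and msw == 0:
        raise DegenerateDataError("zero variance: ICC undefined")
    if average_measure:
        icc = (msb - msw) / msb if msb != 0 else -np.inf
    else:
        icc = (msb - msw) / (msb + (k - 1) * msw)
    return AgreementResult(icc=float(icc), n_pairs=n)
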