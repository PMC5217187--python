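"""Signal-to-concentration conversion for DSC-MRI.

The transverse relaxation-rate change driven by intravascular gadolinium is

    dR2*(t) = -ln(S(t) / S_base) / TE

with S_base the per-voxel mean signal over the pre-bolus baseline window and
TE the echo time in milliseconds, so dR2* carries units of 1/ms.  dR2*(t) is
proportional to the contrast-agent concentration; the proportionality
constant cancels in rCBV, so no absolute conversion is attempted.  Negative
values (signal above baseline, the signature of T1-dominated leakage) are
retained — the leakage correction needs them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bolus_detection import BolusTiming
from .errors import BaselineError, ConversionError
from .io_volumes import DscSeries

__all__ = ["ConcentrationSeries", "baseline_map", "to_concentration"]


@dataclass
class ConcentrationSeries:
    """Per-voxel dR2*(t) curves with their baseline map and bolus timing."""

    delta_r2s: np.ndarray  # (t, z, y, x), units 1/ms; NaN outside mask
    s_base: np.ndarray  # (z, y, x), signal units
    timing: BolusTiming
    frame_spacing: float
    te: float
    mask: np.ndarray  # (z, y, x) bool: voxels with a valid conversion

    @property
    def n_frames(self) -> int:
        return self.delta_r2s.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.delta_r2s.shape[1:]

    def curves(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Concentration curves as a (t, n_voxels) matrix."""
        m = self.mask if mask is None else (mask & self.mask)
        return self.delta_r2s[:, m]


def baseline_map(series: DscSeries, timing: BolusTiming) -> np.ndarray:
    """Per-voxel mean signal over the pre-bolus baseline window."""
    lo, hi = timing.baseline_window
    if hi - lo + 1 < 3:
        raise BaselineError(
            f"baseline window [{lo}, {hi}] shorter than 3 frames"
        )
    return series.signal[lo : hi + 1].mean(axis=0)


def to_concentration(
    series: DscSeries,
    s_base: np.ndarray,
    timing: BolusTiming,
) -> ConcentrationSeries:
    """Convert signal curves to dR2* concentration curves.

    Voxels with non-positive signal at any frame, or non-positive baseline,
    cannot be log-transformed; they are flagged and excluded from the mask.
    Raises :class:`ConversionError` if the baseline is non-positive anywhere
    inside the brain mask.
    """
    s_base = np.asarray(s_base, dtype=float)
    mask = (
        series.brain_mask.copy()
        if series.brain_mask is not None
        else np.ones(series.spatial_shape, dtype=bool)
    )
    if np.any(s_base[mask] <= 0):
        raise ConversionError("non-positive baseline signal inside the brain mask")
    valid = mask & (s_base > 0) & np.all(series.signal > 0, axis=0)
    delta = np.full(series.signal.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta[:, valid] = -np.log(series.signal[:, valid] / s_base[valid]) / series.te
    return ConcentrationSeries(
        delta_r2s=delta,
        s_base=s_base,
        timing=timing,
        frame_spacing=series.frame_spacing,
        te=series.te,
        mask=valid,
    )
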