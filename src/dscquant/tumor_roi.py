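"""Tumor ROI finalization by Otsu thresholding within a user boundary.

A user supplies a generous boundary around the enhancing tumor on the
post-contrast T1-weighted image (already on the DSC grid); the final mask is
the bright class of an Otsu threshold computed from the intensity histogram
restricted to the boundary, keeping the largest connected component.  The
result is invariant under affine rescaling of image intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import DegenerateHistogramError, MaskError
from .io_volumes import LabelVolume

__all__ = ["TumorRoi", "otsu_within_boundary"]

_N_BINS = 256


@dataclass
class TumorRoi:
    """Final tumor mask and the intensity threshold that produced it."""

    mask: np.ndarray  # (z, y, x) bool, subset of the boundary
    threshold_used: float


def otsu_within_boundary(
    t1_post: np.ndarray,
    boundary: LabelVolume | np.ndarray,
    boundary_label: int | None = None,
) -> TumorRoi:
    """Otsu threshold over the boundary's intensity histogram (256 bins).

    ``boundary`` may be a boolean array or a :class:`LabelVolume` (optionally
    with ``boundary_label`` selecting one label; default any non-zero).
    Voxels at or above the threshold are kept; the largest 3D connected
    component survives.
    """
    t1_post = np.asarray(t1_post, dtype=float)
    if isinstance(boundary, LabelVolume):
        b = (
            boundary.labels == boundary_label
            if boundary_label is not None
            else boundary.labels > 0
        )
    else:
        b = np.asarray(boundary, dtype=bool)
    if b.shape != t1_post.shape:
        raise MaskError("boundary and T1 volume shapes differ")
    if not b.any():
        raise MaskError("tumor boundary is empty")
    values = t1_post[b]
    if np.unique(values).size < 2:
        raise DegenerateHistogramError(
            "constant intensity inside the tumor boundary"
        )
    thr = float(threshold_otsu(values, nbins=_N_BINS))
    mask = b & (t1_post >= thr)
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return TumorRoi(mask=mask, threshold_used=thr)
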