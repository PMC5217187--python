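"""NIfTI-1 input/output for DSC series, masks, probability maps and parametric maps.

The internal axis convention is ``(t, z, y, x)`` for 4D dynamic series and
``(z, y, x)`` for 3D volumes, while NIfTI stores ``(x, y, z, t)``; readers and
writers transpose accordingly so spatial content is never permuted.  Voxel
indexing is 0-based; world coordinates are carried by the NIfTI affine.
Parametric maps are written as float32, the standard precision for perfusion
maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import (
    DimensionalityError,
    DscQuantError,
    GridError,
    MetadataError,
)

__all__ = [
    "GridInfo",
    "DscSeries",
    "LabelVolume",
    "ProbabilityMap",
    "read_dsc_series",
    "read_dicom_series",
    "write_dsc_series",
    "read_label_volume",
    "read_probability_map",
    "write_map",
    "check_grid_compatibility",
]


@dataclass(frozen=True)
class GridInfo:
    """Spatial grid: shape in ``(z, y, x)`` order plus the NIfTI affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if self.affine.shape != (4, 4):
            raise GridError(f"affine must be 4x4, got {self.affine.shape}")


@dataclass
class DscSeries:
    """A 4D dynamic susceptibility contrast acquisition.

    Parameters
    ----------
    signal : ndarray, shape (t, z, y, x)
        Dynamic signal intensity in arbitrary scanner units.
    frame_spacing : float
        Seconds between successive dynamic frames.
    te : float
        Echo time in milliseconds.
    brain_mask : ndarray of bool, shape (z, y, x), optional
        Voxels belonging to the brain.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform of the spatial grid.
    """

    signal: np.ndarray
    frame_spacing: float
    te: float
    brain_mask: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise DimensionalityError(
                f"signal must be 4D (t, z, y, x), got {self.signal.ndim}D"
            )
        if self.signal.shape[0] < 8:
            raise DscQuantError(
                f"need at least 8 frames, got {self.signal.shape[0]}"
            )
        if np.nanmin(self.signal) < 0:
            raise DscQuantError("signal intensities must be non-negative")
        if not self.frame_spacing > 0:
            raise MetadataError(f"frame_spacing must be > 0, got {self.frame_spacing}")
        if not self.te > 0:
            raise MetadataError(f"te must be > 0, got {self.te}")
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.spatial_shape:
                raise GridError(
                    f"mask shape {self.brain_mask.shape} != spatial shape "
                    f"{self.spatial_shape}"
                )
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.signal.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[1:]

    @property
    def grid(self) -> GridInfo:
        return GridInfo(self.spatial_shape, self.affine)

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, relative to the first kept frame."""
        return np.arange(self.n_frames) * self.frame_spacing


@dataclass
class LabelVolume:
    """Integer label volume (ROIs, tissue classes) on a series grid."""

    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionalityError("labels must be a 3D volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise DscQuantError("labels must be integer-valued")
            self.labels = rounded.astype(np.int32)
        if self.labels.min() < 0:
            raise DscQuantError("labels must be >= 0")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def grid(self) -> GridInfo:
        return GridInfo(self.labels.shape, self.affine)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class ProbabilityMap:
    """Voxelwise probability volume (e.g. white-matter probability), values in [0, 1]."""

    prob: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        if self.prob.ndim != 3:
            raise DimensionalityError("probability map must be a 3D volume")
        finite = self.prob[np.isfinite(self.prob)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise DscQuantError("probabilities must lie within [0, 1]")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def grid(self) -> GridInfo:
        return GridInfo(self.prob.shape, self.affine)


def _to_internal_4d(data: np.ndarray) -> np.ndarray:
    # NIfTI (x, y, z, t) -> internal (t, z, y, x)
    return np.transpose(data, (3, 2, 1, 0))


def _to_disk_4d(data: np.ndarray) -> np.ndarray:
    return np.transpose(data, (3, 2, 1, 0))


def _to_internal_3d(data: np.ndarray) -> np.ndarray:
    return np.transpose(data, (2, 1, 0))


def _to_disk_3d(data: np.ndarray) -> np.ndarray:
    return np.transpose(data, (2, 1, 0))


def read_dsc_series(
    path: str | Path,
    te: float,
    frame_spacing: float | None = None,
    brain_mask: np.ndarray | None = None,
) -> DscSeries:
    """Read a 4D NIfTI-1 dynamic series.

    The time axis becomes the leading logical axis regardless of on-disk axis
    order.  ``frame_spacing`` is taken from the NIfTI header (``pixdim[4]``)
    when not supplied in the call.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise DimensionalityError(f"{path}: expected a 4D series, got {data.ndim}D")
    if frame_spacing is None:
        zooms = img.header.get_zooms()
        spacing = float(zooms[3]) if len(zooms) > 3 else 0.0
        # pixdim[4] defaults to 1 even when no timing was stored; trust it
        # only when the header declares a time unit.
        t_unit = img.header.get_xyzt_units()[1]
        per_second = {"sec": 1.0, "msec": 1e-3, "usec": 1e-6}
        if t_unit not in per_second or not spacing > 0:
            raise MetadataError(
                f"{path}: frame spacing absent from both header and call"
            )
        frame_spacing = spacing * per_second[t_unit]
    return DscSeries(
        signal=_to_internal_4d(data.astype(float)),
        frame_spacing=float(frame_spacing),
        te=float(te),
        brain_mask=brain_mask,
        affine=img.affine,
    )


def write_dsc_series(series: DscSeries, path: str | Path) -> None:
    """Write a :class:`DscSeries` as a 4D NIfTI-1 file with timing in the header."""
    data = _to_disk_4d(series.signal).astype(np.float32)
    img = nib.Nifti1Image(data, series.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = series.frame_spacing
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def read_dicom_series(
    directory: str | Path, te: float, frame_spacing: float
) -> DscSeries:
    """Thin optional DICOM adapter: read a directory of single-frame 2D+t files.

    Slices are grouped by spatial position and ordered temporally by instance
    number.  Vendor mosaic layouts are not supported.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise DscQuantError(f"no .dcm files in {directory}")
    frames: dict[tuple, list[tuple[int, np.ndarray]]] = {}
    for f in files:
        ds = pydicom.dcmread(str(f))
        pos = tuple(float(v) for v in getattr(ds, "ImagePositionPatient", (0, 0, 0)))
        inst = int(getattr(ds, "InstanceNumber", 0))
        frames.setdefault(pos, []).append((inst, ds.pixel_array.astype(float)))
    positions = sorted(frames, key=lambda p: p[2])  # stack slices by z position
    n_t = {len(v) for v in frames.values()}
    if len(n_t) != 1:
        raise DscQuantError("inconsistent frame count across slice positions")
    stacks = []
    for pos in positions:
        ordered = [arr for _, arr in sorted(frames[pos], key=lambda t: t[0])]
        stacks.append(np.stack(ordered))  # (t, rows, cols)
    signal = np.stack(stacks, axis=1)  # (t, z, rows, cols)
    return DscSeries(signal=signal, frame_spacing=frame_spacing, te=te)


def read_label_volume(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3D label volume")
    return LabelVolume(labels=_to_internal_3d(np.rint(data).astype(np.int32)),
                       affine=img.affine)


def read_probability_map(path: str | Path) -> ProbabilityMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3D probability map")
    return ProbabilityMap(prob=_to_internal_3d(data), affine=img.affine)


def write_map(volume: np.ndarray, path: str | Path, grid: GridInfo) -> None:
    """Write a 3D parametric map as float32 NIfTI-1 (NaN allowed outside the mask)."""
    volume = np.asarray(volume, dtype=np.float32)
    if volume.ndim != 3:
        raise DimensionalityError("parametric map must be 3D")
    if volume.shape != tuple(grid.shape):
        raise GridError(f"map shape {volume.shape} != grid shape {grid.shape}")
    img = nib.Nifti1Image(_to_disk_3d(volume), grid.affine)
    nib.save(img, str(path))


def read_map(path: str | Path) -> tuple[np.ndarray, GridInfo]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3D map")
    vol = _to_internal_3d(data)
    return vol, GridInfo(vol.shape, img.affine)


def check_grid_compatibility(a: GridInfo, b: GridInfo, atol: float = 1e-3) -> bool:
    """True iff spatial shapes match and affines agree within ``atol``."""
    if tuple(a.shape) != tuple(b.shape):
        return False
    return bool(np.allclose(a.affine, b.affine, atol=atol))
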