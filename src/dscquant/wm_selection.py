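"""Normal-appearing white-matter reference selection.

The rCBV normalization needs a white-matter (WM) ROI untouched by tumor.
Two routes are provided:

* **automatic** — voxels are clustered on their post-entrance concentration
  curves with flat-kernel mean shift; the cluster containing the most voxels
  with high WM probability (from an atlas-derived probability map already
  aligned to the DSC grid) is taken, and the ROI is its intersection with the
  high-probability set, minus the tumor ROI;
* **manual** — a user-drawn label volume is intersected with the brain mask
  and the tumor ROI is subtracted.

Curves are z-scored per frame and reduced by PCA (components explaining 95%
of variance) before clustering: bandwidth estimation on the raw ~30-dim
curves is unstable.  The default bandwidth is half the median pairwise
distance of a seeded 500-voxel subsample, keeping the path parameter-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import MeanShift
from sklearn.decomposition import PCA

from .bolus_detection import BolusTiming
from .concentration import ConcentrationSeries
from .errors import EmptyRoiError, LabelError, MaskError, ParameterError
from .io_volumes import LabelVolume, ProbabilityMap

__all__ = [
    "ClusterResult",
    "WmRoi",
    "feature_curves",
    "estimate_bandwidth_median",
    "mean_shift_cluster",
    "select_wm_cluster",
    "manual_wm_roi",
    "automatic_wm_roi",
]

DEFAULT_WM_THRESHOLD = 0.95
_PCA_VARIANCE = 0.95
_BANDWIDTH_SUBSAMPLE = 500
_BANDWIDTH_FACTOR = 0.5


@dataclass
class ClusterResult:
    """Mean-shift segmentation of the brain into tissue classes."""

    label_map: np.ndarray  # (z, y, x) int, -1 outside the clustered mask
    modes: list[np.ndarray]  # per-cluster mean concentration curve
    bandwidth: float
    n_clusters: int


@dataclass
class WmRoi:
    """The white-matter reference region used for rCBV normalization."""

    mask: np.ndarray  # (z, y, x) bool
    source: str  # "automatic" | "manual"
    n_voxels: int


def feature_curves(
    conc: ConcentrationSeries,
    timing: BolusTiming | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel concentration curves truncated to frames >= bolus entrance.

    Returns ``(features, voxel_mask)`` where ``features`` is (n_voxels,
    n_kept_frames) and ``voxel_mask`` marks the voxels with all-finite
    curves (others are excluded from clustering).
    """
    if timing is None:
        timing = conc.timing
    curves = conc.delta_r2s[timing.entrance :]  # (T', z, y, x)
    flat = curves.reshape(curves.shape[0], -1).T  # (n_all, T')
    finite = np.isfinite(flat).all(axis=1)
    voxel_mask = conc.mask.reshape(-1) & finite
    return flat[voxel_mask], voxel_mask.reshape(conc.spatial_shape)


def _reduce_features(features: np.ndarray, seed: int = 0) -> np.ndarray:
    """Per-frame z-scoring followed by PCA to 95% explained variance."""
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    sd[sd == 0] = 1.0
    z = (features - mu) / sd
    n_comp = min(z.shape[0] - 1, z.shape[1])
    if n_comp < 1:
        return z
    pca = PCA(n_components=_PCA_VARIANCE if n_comp > 1 else 1, random_state=seed)
    return pca.fit_transform(z)


def estimate_bandwidth_median(
    features: np.ndarray,
    seed: int = 0,
    subsample: int = _BANDWIDTH_SUBSAMPLE,
    factor: float = _BANDWIDTH_FACTOR,
) -> float:
    """Half the median pairwise distance of a seeded voxel subsample."""
    rng = np.random.default_rng(seed)
    n = features.shape[0]
    idx = rng.choice(n, size=min(subsample, n), replace=False)
    sub = features[idx]
    d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
    tri = d2[np.triu_indices_from(d2, k=1)]
    med = float(np.sqrt(np.median(tri)))
    if med <= 0:
        return 1e-12  # all features identical: any tiny bandwidth yields 1 mode
    return factor * med


def mean_shift_cluster(
    features: np.ndarray,
    bandwidth: float | None = None,
    spatial_mask: np.ndarray | None = None,
    spatial_shape: tuple[int, int, int] | None = None,
    seed: int = 0,
    reduce: bool = True,
) -> ClusterResult:
    """Flat-kernel mean-shift clustering of concentration-curve features.

    ``spatial_mask``/``spatial_shape`` map rows of ``features`` back to
    voxels for the label map; both may be omitted for pure feature-space use,
    in which case the label map is 1D.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 10:
        raise MaskError("need at least 10 voxels to cluster")
    if bandwidth is not None and bandwidth <= 0:
        raise ParameterError(f"bandwidth must be > 0, got {bandwidth}")
    reduced = _reduce_features(features, seed=seed) if reduce else features
    if bandwidth is None:
        bandwidth = estimate_bandwidth_median(reduced, seed=seed)
    ms = MeanShift(bandwidth=bandwidth, bin_seeding=True, cluster_all=True)
    labels = ms.fit_predict(reduced)
    n_clusters = int(labels.max()) + 1
    modes = [features[labels == k].mean(axis=0) for k in range(n_clusters)]
    if spatial_mask is not None and spatial_shape is not None:
        label_map = np.full(spatial_shape, -1, dtype=int)
        label_map[spatial_mask] = labels
    else:
        label_map = labels
    return ClusterResult(
        label_map=label_map,
        modes=modes,
        bandwidth=float(bandwidth),
        n_clusters=n_clusters,
    )


def select_wm_cluster(
    clusters: ClusterResult,
    wm_prob: ProbabilityMap,
    threshold: float = DEFAULT_WM_THRESHOLD,
    tumor_mask: np.ndarray | None = None,
) -> WmRoi:
    """Gate the clustering with the WM probability map.

    Among voxels with probability >= ``threshold`` ("at least 95% WM
    probability" by default), the cluster holding the largest count of such
    voxels is chosen (ties broken toward higher mean probability); the ROI is
    that cluster's high-probability voxels outside the tumor.
    """
    label_map = clusters.label_map
    high = wm_prob.prob >= threshold
    if tumor_mask is not None:
        high = high & ~tumor_mask
    if not high.any():
        raise EmptyRoiError(
            f"no voxel reaches WM probability {threshold:.2f}"
        )
    counts = []
    for k in range(clusters.n_clusters):
        in_k = (label_map == k) & high
        n = int(in_k.sum())
        mean_p = float(wm_prob.prob[in_k].mean()) if n else 0.0
        counts.append((n, mean_p, k))
    n_best, _, k_best = max(counts, key=lambda t: (t[0], t[1], -t[2]))
    if n_best == 0:
        raise EmptyRoiError("no cluster intersects the high-probability WM set")
    roi = (label_map == k_best) & high
    return WmRoi(mask=roi, source="automatic", n_voxels=int(roi.sum()))


def manual_wm_roi(
    mask_volume: LabelVolume,
    label: int,
    brain_mask: np.ndarray | None = None,
    tumor_mask: np.ndarray | None = None,
) -> WmRoi:
    """User-drawn WM ROI: the labelled voxels inside brain, minus tumor."""
    if not np.any(mask_volume.labels == label):
        raise LabelError(f"label {label} absent from the ROI volume")
    roi = mask_volume.labels == label
    if brain_mask is not None:
        roi = roi & brain_mask
    if tumor_mask is not None:
        roi = roi & ~tumor_mask
    if not roi.any():
        raise EmptyRoiError("manual WM ROI empty after brain/tumor exclusions")
    return WmRoi(mask=roi, source="manual", n_voxels=int(roi.sum()))


def automatic_wm_roi(
    conc: ConcentrationSeries,
    wm_prob: ProbabilityMap,
    threshold: float = DEFAULT_WM_THRESHOLD,
    tumor_mask: np.ndarray | None = None,
    bandwidth: float | None = None,
    seed: int = 0,
) -> tuple[WmRoi, ClusterResult]:
    """Full automatic path: features -> mean shift -> probability gating."""
    features, voxel_mask = feature_curves(conc)
    clusters = mean_shift_cluster(
        features,
        bandwidth=bandwidth,
        spatial_mask=voxel_mask,
        spatial_shape=conc.spatial_shape,
        seed=seed,
    )
    roi = select_wm_cluster(clusters, wm_prob, threshold, tumor_mask)
    return roi, clusters
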