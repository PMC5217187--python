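"""End-to-end orchestration of the rCBV quantification pipeline.

Stage order: read series -> discard saturated frames -> brain mask ->
wavelet bolus delineation -> baseline + concentration -> non-enhancing
reference + leakage fit -> trapezoidal CBV -> WM reference ROI (automatic or
manual) -> rCBV normalization -> ROI summaries.  Identical configuration and
inputs produce bit-identical outputs; every resolved parameter is echoed to
the run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bolus_detection as bd
from . import concentration as cc
from . import leakage_cbv as lk
from . import norm_stats as ns
from . import wm_selection as wms
from .errors import DscQuantError, ParameterError
from .io_volumes import (
    DscSeries,
    GridInfo,
    ProbabilityMap,
    read_dsc_series,
    read_label_volume,
    read_probability_map,
    write_map,
)

__all__ = ["RunConfig", "PipelineResult", "quantify", "run_pipeline"]

log = logging.getLogger("dscquant")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    dsc_path: str
    te: float
    frame_spacing: float | None = None
    brain_mask_path: str | None = None
    tumor_roi_path: str | None = None
    wm_mode: str = "auto"  # "auto" | "manual"
    wm_prob_map_path: str | None = None
    wm_roi_path: str | None = None
    wm_label: int = 1
    wm_threshold: float = 0.95
    saturation_frames: int = 3
    wavelet_scales: list[int] = field(default_factory=lambda: list(range(1, 13)))
    min_ridge_length: int = 3
    leakage_correction: bool = True
    per_voxel_bounds: bool = False
    voxel_search_radius: int = 3
    out_dir: str = "dscquant_out"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    timing: bd.BolusTiming
    conc: cc.ConcentrationSeries
    model: lk.LeakageModel | None
    maps: lk.CbvMaps
    wm_roi: wms.WmRoi
    stats: list[ns.RoiStats]


def quantify(
    series: DscSeries,
    tumor_mask: np.ndarray | None = None,
    wm_prob: ProbabilityMap | None = None,
    wm_mode: str = "auto",
    manual_wm_mask: np.ndarray | None = None,
    wm_threshold: float = 0.95,
    saturation_frames: int = 3,
    wavelet_scales: np.ndarray | None = None,
    min_ridge_length: int = 3,
    leakage_correction: bool = True,
    per_voxel_bounds: bool = False,
    voxel_search_radius: int = 3,
    seed: int = 0,
) -> PipelineResult:
    """Run the full quantification on in-memory objects."""
    t0 = time.perf_counter()
    trimmed, timing = bd.detect_bolus(
        series,
        saturation_frames=saturation_frames,
        scales=None if wavelet_scales is None else np.asarray(wavelet_scales),
        min_ridge_length=min_ridge_length,
    )
    log.info(
        "bolus: entrance=%d trough=%d exit=%d (%.2fs)",
        timing.entrance, timing.trough, timing.exit, time.perf_counter() - t0,
    )
    s_base = cc.baseline_map(trimmed, timing)
    conc = cc.to_concentration(trimmed, s_base, timing)
    model = None
    if leakage_correction:
        nonenh = lk.nonenhancing_mask(conc, tumor_mask=tumor_mask)
        model = lk.fit_leakage(conc, lk.build_reference_curve(conc, nonenh))
        log.info("leakage fit on %d reference voxels", int(nonenh.sum()))
    maps = lk.integrate_cbv(
        conc,
        model,
        timing,
        per_voxel_bounds=per_voxel_bounds,
        search_radius=voxel_search_radius,
    )
    if wm_mode == "auto":
        if wm_prob is None:
            raise ParameterError("automatic WM selection needs a probability map")
        wm_roi, _ = wms.automatic_wm_roi(
            conc, wm_prob, threshold=wm_threshold, tumor_mask=tumor_mask, seed=seed
        )
    elif wm_mode == "manual":
        if manual_wm_mask is None:
            raise ParameterError("manual WM selection needs an ROI mask")
        from .io_volumes import LabelVolume

        wm_roi = wms.manual_wm_roi(
            LabelVolume(labels=manual_wm_mask.astype(np.int32)),
            label=1,
            brain_mask=trimmed.brain_mask,
            tumor_mask=tumor_mask,
        )
    else:
        raise ParameterError(f"unknown wm_mode {wm_mode!r}")
    log.info("WM ROI (%s): %d voxels", wm_roi.source, wm_roi.n_voxels)
    maps = ns.normalize_rcbv(maps, wm_roi)
    stats = [ns.roi_stats(maps.rcbv, wm_roi.mask, "wm")]
    if tumor_mask is not None and tumor_mask.any():
        stats.append(ns.roi_stats(maps.rcbv, tumor_mask, "tumor"))
    return PipelineResult(
        timing=timing, conc=conc, model=model, maps=maps, wm_roi=wm_roi, stats=stats
    )


def run_pipeline(config: RunConfig) -> Path:
    """File-to-file pipeline run; returns the output directory.

    Writes CBV/rCBV/K1/K2 maps, the WM ROI, bolus timing JSON, ROI statistics
    CSV and a run log echoing every resolved parameter.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setLevel(logging.INFO)
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        series = read_dsc_series(
            config.dsc_path, te=config.te, frame_spacing=config.frame_spacing
        )
        if config.brain_mask_path:
            series.brain_mask = read_label_volume(config.brain_mask_path).labels > 0
        tumor_mask = None
        if config.tumor_roi_path:
            tumor_mask = read_label_volume(config.tumor_roi_path).labels > 0
        wm_prob = None
        if config.wm_prob_map_path:
            wm_prob = read_probability_map(config.wm_prob_map_path)
        manual_wm = None
        if config.wm_roi_path:
            manual_wm = (
                read_label_volume(config.wm_roi_path).labels == config.wm_label
            ).astype(np.int32)
        try:
            result = quantify(
                series,
                tumor_mask=tumor_mask,
                wm_prob=wm_prob,
                wm_mode=config.wm_mode,
                manual_wm_mask=manual_wm,
                wm_threshold=config.wm_threshold,
                saturation_frames=config.saturation_frames,
                wavelet_scales=np.asarray(config.wavelet_scales),
                min_ridge_length=config.min_ridge_length,
                leakage_correction=config.leakage_correction,
                per_voxel_bounds=config.per_voxel_bounds,
                voxel_search_radius=config.voxel_search_radius,
                seed=config.seed,
            )
        except DscQuantError as err:
            raise type(err)(
                f"pipeline failed: {err} "
                "(check input grids, timing metadata and mask coverage)"
            ) from err
        grid = GridInfo(series.spatial_shape, series.affine)
        write_map(result.maps.cbv_uncorrected, out / "cbv_uncorrected.nii.gz", grid)
        write_map(result.maps.cbv_corrected, out / "cbv_corrected.nii.gz", grid)
        write_map(result.maps.rcbv, out / "rcbv.nii.gz", grid)
        if result.maps.k1_map is not None:
            write_map(result.maps.k1_map, out / "k1.nii.gz", grid)
            write_map(result.maps.k2_map, out / "k2.nii.gz", grid)
        write_map(result.wm_roi.mask.astype(np.float32), out / "wm_roi.nii.gz", grid)
        timing = result.timing
        (out / "bolus_timing.json").write_text(
            json.dumps(
                {
                    "n_discarded": timing.n_discarded,
                    "baseline_window": list(timing.baseline_window),
                    "entrance": timing.entrance,
                    "trough": timing.trough,
                    "exit": timing.exit,
                },
                indent=2,
            )
        )
        rows = [dataclasses.asdict(s) for s in result.stats]
        pd.DataFrame(rows).to_csv(out / "roi_stats.csv", index=False)
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
        log.info("outputs written to %s", out)
        return out
    finally:
        log.removeHandler(handler)
        handler.close()
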