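"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes: simulate/load -> contrast volumes -> SSADA ->
segmentation -> projections -> channel detection (-> optional injury
metrics), logging each stage with its timing, and optionally persisting
every artifact plus a JSON provenance record (config, hash, versions, seed)
to an output directory.  All stage functions are pure data-in/data-out, so
CLI subcommands that re-run a single stage on stored intermediates reproduce
the full run bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import numpy as np

from . import angiography, io, phantom, projections, quantify, segmentation, signals
from .config import PipelineConfig
from .core import ConfigError, DerivedVolume, PolTomogramSeries, StageError, substream
from .segmentation import BoundarySet

logger = logging.getLogger("mfoct")

__all__ = [
    "run_pipeline",
    "stage_simulate",
    "stage_signals",
    "stage_angio",
    "stage_segment",
    "stage_project",
    "stage_channels",
    "stage_tbi",
]


def _versions() -> dict:
    import h5py
    import scipy
    import skimage

    from . import __version__

    return {
        "mfoct": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "h5py": h5py.__version__,
    }


def stage_simulate(config: PipelineConfig):
    scene = phantom.build_scene(config.scene, config.seed)
    acq = config.acquisition.to_acquisition()
    series, truth = phantom.render_series(scene, acq, snr_db=config.snr_db, seed=config.seed)
    return scene, series, truth


def stage_signals(config: PipelineConfig, series: PolTomogramSeries) -> dict[str, DerivedVolume]:
    out = {
        "intensity_db": signals.compute_intensity(series, scale="dB"),
        "retardation": signals.compute_retardation(series),
        "dopu": signals.compute_dopu(series, kernel=tuple(config.dopu_kernel)),
    }
    if tuple(config.seg_dopu_kernel) != tuple(config.dopu_kernel):
        out["dopu_seg"] = signals.compute_dopu(series, kernel=tuple(config.seg_dopu_kernel))
    else:
        out["dopu_seg"] = out["dopu"]
    return out


def stage_angio(config: PipelineConfig, series: PolTomogramSeries, intensity_db: DerivedVolume) -> DerivedVolume:
    series.require_repeats(2)
    bands = angiography.split_spectrum(series, m=config.ssada.m_bands, overlap=config.ssada.overlap)
    floor = signals.estimate_noise_floor_db(intensity_db) + config.ssada.floor_offset_db
    return angiography.ssada_decorrelation(bands, intensity_db=intensity_db, floor_db=floor)


def stage_segment(config: PipelineConfig, vols: dict[str, DerivedVolume]):
    return segmentation.segment_volume(vols["intensity_db"], vols["dopu_seg"], config.segmentation)


def stage_project(
    config: PipelineConfig,
    vols: dict[str, DerivedVolume],
    octa: DerivedVolume | None,
    boundaries: BoundarySet,
) -> dict:
    out: dict = {}
    out["fused_bscans"] = projections.fuse_dopu_intensity(
        vols["intensity_db"], vols["dopu"], config.dopu_colormap
    )
    for layer in ("skin", "skull", "brain"):
        out[f"{layer}_intensity"] = projections.layer_projection(vols["intensity_db"], layer, boundaries)
        ret = projections.layer_projection(vols["retardation"], layer, boundaries)
        out[f"{layer}_retardation"] = ret
        out[f"{layer}_retardation_gray"] = projections.retardation_grayscale(ret)
    if octa is not None:
        extra, intra = projections.split_extra_intra(octa, boundaries)
        out["extracranial_octa"] = extra
        out["intracranial_octa"] = intra
        out["merged_rgb"] = projections.merge_red_green(extra, intra)
        for tag, img in (("extracranial", extra), ("intracranial", intra)):
            out[f"{tag}_depth_rgb"] = projections.depth_encode(
                octa, tag, boundaries, config.depth_colormap
            )
    return out


def calibrate_bin_threshold(config: PipelineConfig) -> float:
    """99th-percentile static-tissue decorrelation from a vessel-free run."""
    calib_scene_cfg = config.scene.model_copy(
        update={"vessels": phantom.VesselConfig(n_skin=0, n_intracranial=0, n_transcranial=0)}
    )
    seed = int(substream(config.seed, "calibration").integers(2**31))
    scene = phantom.build_scene(calib_scene_cfg, seed)
    series, _ = phantom.render_series(
        scene, config.acquisition.to_acquisition(), snr_db=config.snr_db, seed=seed, n_repeats=2
    )
    vols = stage_signals(config, series)
    octa = stage_angio(config, series, vols["intensity_db"])
    boundaries, _ = stage_segment(config, vols)
    upper, lower = quantify.skull_half_projections(octa, boundaries)
    pix = np.concatenate([upper.pixels.ravel(), lower.pixels.ravel()])
    return quantify.calibrate_flow_threshold(pix, config.quantify.calibration_quantile)


def stage_channels(
    config: PipelineConfig,
    octa: DerivedVolume,
    boundaries: BoundarySet,
    proj: dict,
    bin_threshold: float | None = None,
) -> dict:
    q = config.quantify
    upper, lower = quantify.skull_half_projections(octa, boundaries)
    thr = bin_threshold if bin_threshold is not None else q.bin_threshold
    if thr is None:
        thr = calibrate_bin_threshold(config)
    calls = quantify.detect_channels(upper, lower, bin_threshold=thr, min_area=q.min_area_px)
    int_proj = proj["skull_intensity"]
    int_thr = q.int_threshold_db
    if int_thr is None:
        int_thr = float(np.nanmedian(int_proj.pixels))
    sutures = quantify.build_suture_map(
        proj["skull_retardation"], int_proj, ret_threshold_deg=q.ret_threshold_deg, int_threshold_db=int_thr
    )
    calls, fraction = quantify.colocalize(calls, sutures, dilation_px=q.colocalization_dilation_px)
    return {
        "upper": upper,
        "lower": lower,
        "calls": calls,
        "sutures": sutures,
        "suture_fraction": fraction,
        "bin_threshold": thr,
    }


def stage_tbi(config: PipelineConfig) -> dict:
    """Simulated injury time series + metrics (synthetic timepoints)."""
    q = config.quantify
    nz, nx, ny = config.scene.grid_shape
    roi = q.tbi_roi or (nx // 4, 3 * nx // 4, ny // 4, 3 * ny // 4)
    items = phantom.make_tbi_series(config.scene, list(q.tbi_fractions), roi, config.seed)
    acq = config.acquisition.to_acquisition()
    series_list = []
    boundaries = None
    for t, scene, colmask in items:
        series, truth = phantom.render_series(scene, acq, snr_db=config.snr_db, seed=config.seed, n_repeats=2)
        vols = stage_signals(config, series)
        octa = stage_angio(config, series, vols["intensity_db"])
        if boundaries is None:
            boundaries, _ = stage_segment(config, vols)
        series_list.append((t, octa))
    thr = q.tbi_flow_threshold
    if thr is None:
        first = quantify.band_max_projection(
            series_list[0][1], "brain", boundaries, max_thickness_px=q.tbi_band_thickness_px
        )
        # calibrate on pixels outside the ROI of the first timepoint
        mask = np.ones_like(first, dtype=bool)
        x0, x1, y0, y1 = roi
        mask[x0:x1, y0:y1] = False
        thr = quantify.calibrate_flow_threshold(first[mask], q.calibration_quantile)
    metrics = quantify.tbi_metrics(
        series_list, roi, thr, boundaries=boundaries, band="brain", band_thickness_px=q.tbi_band_thickness_px
    )
    return {"metrics": metrics, "roi": roi, "flow_threshold": thr}


def _persist(bundle: dict, config: PipelineConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(config.json_canonical())
    attrs = {"config_hash": chash}
    if "series" in bundle:
        io.write_tomogram(out_dir / "tomogram.h5", bundle["series"], extra_attrs=attrs)
    for key in ("intensity_db", "retardation", "dopu", "dopu_seg"):
        if key in bundle:
            io.write_volume(out_dir / f"{key}.h5", bundle[key], extra_attrs=attrs)
    if bundle.get("octa") is not None:
        io.write_volume(out_dir / "octa.h5", bundle["octa"], extra_attrs=attrs)
    if "boundaries" in bundle:
        io.write_boundaries(out_dir / "boundaries.h5", bundle["boundaries"], extra_attrs=attrs)
        io.boundaries_to_csv(out_dir / "boundaries.csv", bundle["boundaries"])
    if "layers" in bundle:
        io.write_layer_masks(out_dir / "layer_masks.tif", bundle["layers"])
    for key, img in bundle.get("projections", {}).items():
        if isinstance(img, projections.EnFaceImage):
            io.write_enface_png(out_dir / f"{key}.png", img)
            io.write_enface_tiff(out_dir / f"{key}.tif", img)
    chan = bundle.get("channels")
    if chan:
        calls = chan["calls"]
        rows = [
            {
                "label": c.label,
                "centroid_x": c.centroid_xy[0],
                "centroid_y": c.centroid_xy[1],
                "area_px": c.area_px,
                "inside_suture": c.inside_suture,
            }
            for c in calls.components
        ]
        io.write_json(
            out_dir / "channels.json",
            {
                "components": rows,
                "suture_fraction": chan["suture_fraction"],
                "bin_threshold": chan["bin_threshold"],
                "config_hash": chash,
            },
        )
    tbi = bundle.get("tbi")
    if tbi:
        io.write_json(
            out_dir / "tbi_metrics.json",
            {
                "roi": list(tbi["roi"]),
                "flow_threshold": tbi["flow_threshold"],
                "metrics": [
                    {
                        "timepoint_h": m.timepoint,
                        "vessel_density": m.vessel_density,
                        "avascular_area_px": m.avascular_area_px,
                    }
                    for m in tbi["metrics"]
                ],
                "config_hash": chash,
            },
        )


def run_pipeline(
    config: PipelineConfig,
    in_path: str | Path | None = None,
    simulate: bool = False,
    out_dir: str | Path | None = None,
    with_tbi: bool = False,
) -> dict:
    """Run every stage; returns the artifact bundle.

    Exactly one of ``in_path`` / ``simulate`` selects the input.  With
    ``out_dir`` all artifacts plus a provenance record are persisted; a stage
    failure still persists partial provenance, then re-raises as
    :class:`StageError`.
    """
    if simulate == (in_path is not None):
        raise ConfigError("provide exactly one of in_path or simulate=True")
    out_dir = Path(out_dir) if out_dir is not None else None
    provenance: dict = {
        "config": json.loads(config.json_canonical()),
        "config_hash": io.config_hash(config.json_canonical()),
        "seed": config.seed,
        "versions": _versions(),
        "stages": [],
    }

    def persist_provenance():
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            io.write_json(out_dir / "provenance.json", provenance)

    bundle: dict = {}

    def run_stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except (ConfigError,) as e:
            provenance["stages"].append({"name": name, "status": "config-error", "error": str(e)})
            persist_provenance()
            raise
        except Exception as e:
            provenance["stages"].append({"name": name, "status": "failed", "error": str(e)})
            persist_provenance()
            raise StageError(name, str(e)) from e
        dt = time.perf_counter() - t0
        provenance["stages"].append({"name": name, "status": "ok", "seconds": round(dt, 3)})
        logger.info("stage %-10s done in %.2fs", name, dt)
        return result

    if simulate:
        scene, series, truth = run_stage("simulate", lambda: stage_simulate(config))
        bundle.update(scene=scene, series=series, truth=truth)
    else:
        series = run_stage("load", lambda: io.read_tomogram(in_path))
        bundle["series"] = series

    vols = run_stage("signals", lambda: stage_signals(config, series))
    bundle.update(vols)

    bundle["octa"] = run_stage("angio", lambda: stage_angio(config, series, vols["intensity_db"]))

    boundaries, layers = run_stage("segment", lambda: stage_segment(config, vols))
    bundle.update(boundaries=boundaries, layers=layers)

    bundle["projections"] = run_stage(
        "project", lambda: stage_project(config, vols, bundle["octa"], boundaries)
    )

    if bundle["octa"] is not None:
        bundle["channels"] = run_stage(
            "channels",
            lambda: stage_channels(config, bundle["octa"], boundaries, bundle["projections"]),
        )

    if with_tbi:
        bundle["tbi"] = run_stage("tbi", lambda: stage_tbi(config))

    if out_dir is not None:
        run_stage("persist", lambda: _persist(bundle, config, out_dir))
        persist_provenance()
    return bundle
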