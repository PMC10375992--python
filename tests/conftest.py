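"""Shared fixtures: small, fast phantom configurations and rendered bundles.

Unit tests run on reduced grids (~128 x 96 x 32) so the default suite stays
fast; the acceptance tests use the full default grid.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from mfoct import phantom, pipeline, signals
from mfoct.config import PipelineConfig
from mfoct.core import Acquisition, PolTomogramSeries
from mfoct.phantom import (
    LayerOptics,
    PigmentConfig,
    SceneConfig,
    SutureConfig,
    VesselConfig,
)

warnings.filterwarnings("ignore", message="zero noise floor")


SMALL_GRID = (128, 96, 32)


def small_scene_config(**overrides) -> SceneConfig:
    """Reduced-grid variant of the default scene."""
    base = dict(
        grid_shape=SMALL_GRID,
        depth_air_skin=16.0,
        depth_skin_skull=36.0,
        depth_skull_brain=72.0,
        undulation_amplitude=2.0,
        pigment=PigmentConfig(n_spots=4, base_sheet=True),
        vessels=VesselConfig(n_skin=2, n_intracranial=2, n_transcranial=2),
    )
    base.update(overrides)
    return SceneConfig(**base)


def quiet_optics(**overrides) -> dict:
    """Layer optics with no birefringence/depolarization/attenuation."""
    base = dict(
        skin=LayerOptics(backscatter=1.0, attenuation_per_um=0.0, birefringence_dn=0.0),
        skull=LayerOptics(backscatter=2.0, attenuation_per_um=0.0, birefringence_dn=0.0),
        brain=LayerOptics(backscatter=0.5, attenuation_per_um=0.0, birefringence_dn=0.0),
        suture=SutureConfig(enabled=False),
        pigment=PigmentConfig(n_spots=0, base_sheet=False),
        vessels=VesselConfig(n_skin=0, n_intracranial=0, n_transcranial=0),
        undulation_amplitude=0.0,
    )
    base.update(overrides)
    return base


def make_tomo(h: np.ndarray, v: np.ndarray, n_repeats: int | None = None) -> PolTomogramSeries:
    h = np.asarray(h, np.complex64)
    v = np.asarray(v, np.complex64)
    if h.ndim == 3:
        h, v = h[None], v[None]
    acq = Acquisition(n_repeats=n_repeats or h.shape[0])
    return PolTomogramSeries(h=h, v=v, acquisition=acq)


def boundary_rmse(b, truth) -> dict[str, float]:
    ok = b.valid.all(axis=0)
    out = {}
    for name, est, tr in (
        ("air_skin", b.z_air_skin, truth.z_air_skin),
        ("skin_skull", b.z_skin_skull, truth.z_skin_skull),
        ("skull_brain", b.z_skull_brain, truth.z_skull_brain),
    ):
        out[name] = float(np.sqrt(np.mean((est[ok] - tr[ok]) ** 2)))
    return out


def layer_accuracy(b, truth, nz: int) -> float:
    """4-class (air/skin/skull/brain) voxel label accuracy in valid columns."""
    zz = np.arange(nz)[:, None, None]

    def rh(z):
        return np.floor(z + 0.5).astype(int)

    def labels(z0, z1, z2):
        return (zz >= rh(z0)).astype(np.int8) + (zz >= rh(z1)) + (zz >= rh(z2))

    lt = labels(truth.z_air_skin, truth.z_skin_skull, truth.z_skull_brain)
    le = labels(b.z_air_skin, b.z_skin_skull, b.z_skull_brain)
    ok = b.valid.all(axis=0)
    return float((lt == le)[:, ok].mean())


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(scene=small_scene_config(), seed=101)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """Rendered small phantom + derived volumes + segmentation, reused widely."""
    cfg = small_config
    scene = phantom.build_scene(cfg.scene, cfg.seed)
    series, truth = phantom.render_series(
        scene, cfg.acquisition.to_acquisition(), snr_db=25.0, seed=cfg.seed, n_repeats=2
    )
    vols = pipeline.stage_signals(cfg, series)
    octa = pipeline.stage_angio(cfg, series, vols["intensity_db"])
    boundaries, layers = pipeline.stage_segment(cfg, vols)
    return {
        "config": cfg,
        "scene": scene,
        "series": series,
        "truth": truth,
        "vols": vols,
        "octa": octa,
        "boundaries": boundaries,
        "layers": layers,
    }


@pytest.fixture(scope="session")
def quiet_render():
    """Flat, noise-free, polarization-quiet phantom for exact checks."""
    cfg = SceneConfig(grid_shape=SMALL_GRID, depth_air_skin=16, depth_skin_skull=36,
                      depth_skull_brain=72, **quiet_optics())
    scene = phantom.build_scene(cfg, seed=7)
    series, truth = phantom.render_series(scene, snr_db=None, seed=7, n_repeats=2)
    return cfg, scene, series, truth
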