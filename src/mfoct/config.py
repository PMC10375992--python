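"""Pipeline configuration: a single schema-validated object that round-trips
losslessly through JSON and seeds every stage's randomness."""

from __future__ import annotations

from pathlib import Path

from pydantic import BaseModel, Field, ValidationError

from .core import Acquisition, ConfigError
from .phantom import SceneConfig
from .segmentation import SegmentationParams

__all__ = ["AcquisitionConfig", "SsadaParams", "QuantifyParams", "PipelineConfig", "load_config"]


class AcquisitionConfig(BaseModel):
    pitch_z_um: float = 3.4
    pitch_x_um: float = 8.0
    pitch_y_um: float = 8.0
    wavelength_um: float = 1.3
    n_repeats: int = Field(default=4, ge=1)
    line_rate_hz: float = 25_000.0

    def to_acquisition(self) -> Acquisition:
        return Acquisition(**self.model_dump())


class SsadaParams(BaseModel):
    m_bands: int = Field(default=4, ge=1)
    overlap: float = Field(default=0.5, ge=0.0, lt=1.0)
    floor_offset_db: float = 12.0  # intensity floor = air median + this


class QuantifyParams(BaseModel):
    bin_threshold: float | None = None  # None -> calibrated from a vessel-free run
    calibration_quantile: float = Field(default=0.99, gt=0, lt=1)
    min_area_px: int = Field(default=4, ge=1)
    colocalization_dilation_px: int = Field(default=2, ge=0)
    ret_threshold_deg: float = 32.0
    int_threshold_db: float | None = None  # None -> median of the skull projection
    tbi_fractions: tuple[float, ...] = (0.05, 0.15, 0.30)
    tbi_roi: tuple[int, int, int, int] | None = None  # None -> centered box
    tbi_flow_threshold: float | None = None  # None -> calibrated
    tbi_band_thickness_px: int | None = 20  # clip the brain band for flow binarization


class PipelineConfig(BaseModel):
    """Everything one end-to-end run needs, plus the single rng seed."""

    acquisition: AcquisitionConfig = AcquisitionConfig()
    scene: SceneConfig = SceneConfig()
    snr_db: float | None = 25.0
    dopu_kernel: tuple[int, int] = (5, 5)  # contrast-volume DOPU
    seg_dopu_kernel: tuple[int, int] = (1, 9)  # lateral-only: no axial boundary bleed
    segmentation: SegmentationParams = SegmentationParams()
    ssada: SsadaParams = SsadaParams()
    quantify: QuantifyParams = QuantifyParams()
    dopu_colormap: dict[str, float] = {"h0": 1.0 / 3.0, "h1": 0.0}
    depth_colormap: dict[str, float] = {"h0": 2.0 / 3.0, "h1": 0.0}
    seed: int = 0

    def json_canonical(self) -> str:
        return self.model_dump_json()


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    try:
        return PipelineConfig.model_validate_json(Path(path).read_text())
    except (OSError, ValidationError, ValueError) as e:
        raise ConfigError(f"invalid pipeline config {path}: {e}") from e
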