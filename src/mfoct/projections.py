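"""Rendered outputs: fused B-scans, layer projections, and OCTA composites.

Depth bands are always defined by a :class:`~mfoct.segmentation.BoundarySet`
and are half-open ``[upper, lower)`` in voxel rows, so every projection is
invariant to padding the volume with extra air rows (provided the boundaries
shift with it).  Rendering never mutates its input volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .core import ConfigError, DerivedVolume, same_grid
from .segmentation import BoundarySet

__all__ = [
    "EnFaceImage",
    "band_bounds",
    "layer_projection",
    "fuse_dopu_intensity",
    "retardation_grayscale",
    "split_extra_intra",
    "merge_red_green",
    "depth_encode",
    "DEFAULT_DOPU_CMAP",
    "DEFAULT_DEPTH_CMAP",
]

# hue ramps in matplotlib HSV units; h0 applies at value 0, h1 at value 1
DEFAULT_DOPU_CMAP = {"h0": 1.0 / 3.0, "h1": 0.0}  # green at low DOPU -> red
DEFAULT_DEPTH_CMAP = {"h0": 2.0 / 3.0, "h1": 0.0}  # blue shallow -> red deep

LAYER_TAGS = (
    "skin",
    "skull",
    "brain",
    "extracranial",
    "intracranial",
    "upper_skull",
    "lower_skull",
)


@dataclass
class EnFaceImage:
    """2-D projection over a boundary-defined depth band."""

    pixels: np.ndarray  # (nx, ny) scalar or (nx, ny, 3) RGB
    kind: str
    layer_tag: str = ""
    units: str = ""
    provenance: dict | None = None

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3


def band_bounds(b: BoundarySet, nz: int, tag: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(upper, lower, valid) fractional depth bounds for a named band."""
    mid = b.z_midline
    if tag == "skin":
        lo, hi, ok = b.z_air_skin, b.z_skin_skull, b.valid[0] & b.valid[1]
    elif tag == "skull":
        lo, hi, ok = b.z_skin_skull, b.z_skull_brain, b.valid[1] & b.valid[2]
    elif tag == "brain":
        lo, hi, ok = b.z_skull_brain, np.full_like(b.z_skull_brain, float(nz)), b.valid[2]
    elif tag == "extracranial":
        lo, hi, ok = b.z_air_skin, mid, b.valid[0] & b.midline_valid
    elif tag == "intracranial":
        lo, hi, ok = mid, np.full_like(mid, float(nz)), b.midline_valid
    elif tag == "upper_skull":
        lo, hi, ok = b.z_skin_skull, mid, b.valid[1] & b.midline_valid
    elif tag == "lower_skull":
        lo, hi, ok = mid, b.z_skull_brain, b.valid[2] & b.midline_valid
    else:
        raise ConfigError(f"unknown layer tag '{tag}'")
    return np.asarray(lo, float), np.asarray(hi, float), np.asarray(ok, bool)


def _band_rows(lo: np.ndarray, hi: np.ndarray, nz: int) -> tuple[np.ndarray, np.ndarray]:
    r_lo = np.clip(np.floor(np.nan_to_num(lo, nan=0.0) + 0.5).astype(int), 0, nz)
    r_hi = np.clip(np.floor(np.nan_to_num(hi, nan=0.0) + 0.5).astype(int), 0, nz)
    return r_lo, np.maximum(r_hi, r_lo)


def layer_projection(
    volume: DerivedVolume, band: str, b: BoundarySet, stat: str = "mean"
) -> EnFaceImage:
    """Per-column mean of the volume inside a half-open depth band.

    Columns with an invalid or empty band become NaN (no-data) pixels.
    """
    if stat != "mean":
        raise ConfigError("only the mean statistic is supported")
    nz = volume.shape[0]
    lo, hi, ok = band_bounds(b, nz, band)
    r_lo, r_hi = _band_rows(lo, hi, nz)
    vals = volume.values.astype(np.float64)
    cs = np.concatenate([np.zeros((1,) + vals.shape[1:]), np.cumsum(vals, axis=0)], axis=0)
    sums = np.take_along_axis(cs, r_hi[None], axis=0)[0] - np.take_along_axis(cs, r_lo[None], axis=0)[0]
    counts = (r_hi - r_lo).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mean = np.where(ok & (counts > 0), mean, np.nan)
    if np.all(np.isnan(mean)):
        warnings.warn(f"band '{band}' produced no data")
    kind = {"decorrelation": "octa_mean"}.get(volume.kind, f"mean_{volume.kind}")
    units = {"intensity_dB": "dB", "retardation_deg": "deg"}.get(volume.kind, "")
    return EnFaceImage(pixels=mean.astype(np.float32), kind=kind, layer_tag=band, units=units)


def _window(db: np.ndarray, lo_pct: float = 1.0, hi_pct: float = 99.0) -> np.ndarray:
    finite = db[np.isfinite(db)]
    if finite.size == 0:
        return np.zeros_like(db)
    p1, p99 = np.percentile(finite, [lo_pct, hi_pct])
    if p99 <= p1:
        return np.zeros_like(db)
    return np.clip((db - p1) / (p99 - p1), 0.0, 1.0)


def fuse_dopu_intensity(
    intensity: DerivedVolume,
    dopu: DerivedVolume,
    colormap_spec: dict | None = None,
) -> np.ndarray:
    """DOPU-Intensity fused RGB B-scan stack, shape (nz, nx, ny, 3).

    Hue follows DOPU (low DOPU lands on the green end by default), brightness
    is percentile-windowed intensity, saturation is 1 -- so strongly
    reflecting, depolarizing pigment renders bright green.
    """
    same_grid(intensity.shape, dopu.shape)
    cmap = colormap_spec or DEFAULT_DOPU_CMAP
    d = np.clip(dopu.values, 0.0, 1.0)
    hue = cmap["h0"] + (cmap["h1"] - cmap["h0"]) * d
    value = _window(intensity.values)
    hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
    return hsv_to_rgb(hsv).astype(np.float32)


def retardation_grayscale(proj: EnFaceImage) -> EnFaceImage:
    """Linear rescale of a retardation projection: [0, 90] deg -> [0, 1]."""
    if "retardation" not in proj.kind:
        raise ConfigError("retardation_grayscale expects a retardation projection")
    gray = np.clip(proj.pixels / 90.0, 0.0, 1.0).astype(np.float32)
    gray = np.where(np.isfinite(proj.pixels), gray, np.nan)
    return EnFaceImage(pixels=gray, kind="retardation_gray", layer_tag=proj.layer_tag)


def split_extra_intra(octa: DerivedVolume, b: BoundarySet) -> tuple[EnFaceImage, EnFaceImage]:
    """Mean OCTA projections above/below the cranial midline."""
    extra = layer_projection(octa, "extracranial", b)
    intra = layer_projection(octa, "intracranial", b)
    return extra, intra


def _normalize(pixels: np.ndarray, pct: float = 99.5) -> np.ndarray:
    finite = pixels[np.isfinite(pixels)]
    top = np.percentile(finite, pct) if finite.size else 0.0
    if top <= 0:
        top = float(np.nanmax(pixels)) if finite.size else 1.0
    if top <= 0:
        top = 1.0
    return np.clip(np.nan_to_num(pixels, nan=0.0) / top, 0.0, 1.0)


def merge_red_green(extra: EnFaceImage, intra: EnFaceImage) -> EnFaceImage:
    """Red = extracranial, green = intracranial; overlap renders yellow."""
    same_grid(extra.pixels.shape, intra.pixels.shape)
    r = _normalize(extra.pixels)
    g = _normalize(intra.pixels)
    rgb = np.stack([r, g, np.zeros_like(r)], axis=-1).astype(np.float32)
    return EnFaceImage(pixels=rgb, kind="merged_rgb", layer_tag="extracranial+intracranial")


def depth_encode(
    octa: DerivedVolume,
    band: str,
    b: BoundarySet,
    colormap_spec: dict | None = None,
) -> EnFaceImage:
    """Depth-color-encoded OCTA: hue from the decorrelation-weighted mean
    relative depth inside the band, brightness from the band's peak
    decorrelation.  Columns without flow are black."""
    cmap = colormap_spec or DEFAULT_DEPTH_CMAP
    nz = octa.shape[0]
    lo, hi, ok = band_bounds(b, nz, band)
    r_lo, r_hi = _band_rows(lo, hi, nz)
    zz = np.arange(nz)[:, None, None]
    in_band = (zz >= r_lo[None]) & (zz < r_hi[None]) & ok[None]
    d = np.where(in_band, octa.values, 0.0)
    dsum = d.sum(axis=0)
    # normalize by the deepest row in the band so both endpoints are reachable
    span = np.maximum(r_hi - 1 - r_lo, 1).astype(float)
    rel = np.clip((zz - r_lo[None]) / span[None], 0.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(dsum > 0, (d * rel).sum(axis=0) / np.maximum(dsum, 1e-30), 0.0)
    dmax = d.max(axis=0)
    top = dmax.max()
    value = dmax / top if top > 0 else np.zeros_like(dmax)
    hue = cmap["h0"] + (cmap["h1"] - cmap["h0"]) * t
    hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
    rgb = hsv_to_rgb(hsv).astype(np.float32)
    rgb[~ok] = 0.0
    return EnFaceImage(pixels=rgb, kind="octa_depth_rgb", layer_tag=band)
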