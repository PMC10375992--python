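"""Transcranial-channel detection, suture mapping, and injury metrics.

A transcranial channel is a vessel present in both the upper and lower halves
of the skull at the same en-face position, so the intersection of the two
half-skull angiogram projections marks the channels.  The suture map is
built from the skull-band projections (high intensity, low retardation), and
channels are co-localized against it.  Injury metrics quantify the en-face
vessel coverage of an ROI over a time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .core import ConfigError, DerivedVolume, same_grid
from .projections import EnFaceImage, layer_projection
from .segmentation import BoundarySet

__all__ = [
    "ChannelComponent",
    "ChannelCallSet",
    "SutureMap",
    "VesselMetrics",
    "skull_half_projections",
    "detect_channels",
    "build_suture_map",
    "colocalize",
    "tbi_metrics",
    "calibrate_flow_threshold",
]


@dataclass
class ChannelComponent:
    label: int
    centroid_xy: tuple[float, float]
    area_px: int
    inside_suture: bool | None = None


@dataclass
class ChannelCallSet:
    channel_mask: np.ndarray  # (nx, ny) bool
    components: list[ChannelComponent]
    params: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return len(self.components)


@dataclass
class SutureMap:
    suture_mask: np.ndarray  # (nx, ny) bool
    source: dict = field(default_factory=dict)


@dataclass
class VesselMetrics:
    timepoint: float
    roi: tuple[int, int, int, int]
    vessel_density: float
    avascular_area_px: int


def skull_half_projections(
    octa: DerivedVolume, b: BoundarySet
) -> tuple[EnFaceImage, EnFaceImage]:
    """Mean OCTA projections of the upper/lower skull halves.

    Columns with a degenerate skull (thickness < 2 voxels) become no-data.
    """
    upper = layer_projection(octa, "upper_skull", b)
    lower = layer_projection(octa, "lower_skull", b)
    thin = (b.z_skull_brain - b.z_skin_skull) < 2
    for img in (upper, lower):
        img.pixels = np.where(thin, np.nan, img.pixels)
    return upper, lower


def detect_channels(
    upper: EnFaceImage,
    lower: EnFaceImage,
    bin_threshold: float,
    min_area: int = 4,
) -> ChannelCallSet:
    """Intersection of the binarized half-skull angiograms.

    Components smaller than ``min_area`` pixels are discarded (single-pixel
    speckle coincidences); the rest are labeled with centroids.
    """
    same_grid(upper.pixels.shape, lower.pixels.shape)
    up = np.nan_to_num(upper.pixels, nan=-np.inf) >= bin_threshold
    lo = np.nan_to_num(lower.pixels, nan=-np.inf) >= bin_threshold
    mask = up & lo
    if min_area > 1:
        mask = _drop_small_2d(mask, min_area)
    labels = measure.label(mask, connectivity=2)
    comps = [
        ChannelComponent(
            label=int(r.label),
            centroid_xy=(float(r.centroid[0]), float(r.centroid[1])),
            area_px=int(r.area),
        )
        for r in measure.regionprops(labels)
    ]
    return ChannelCallSet(
        channel_mask=mask,
        components=comps,
        params={"bin_threshold": float(bin_threshold), "min_area": int(min_area)},
    )


def _drop_small_2d(mask: np.ndarray, min_area: int) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    keep = counts >= min_area
    keep[0] = False
    return keep[labels]


def build_suture_map(
    skull_retardation_proj: EnFaceImage,
    skull_intensity_proj: EnFaceImage,
    ret_threshold_deg: float,
    int_threshold_db: float,
    opening_width: int = 3,
    min_area: int = 8,
    median_width: int = 3,
) -> SutureMap:
    """Sutures = low retardation AND high intensity within the skull band.

    A small median filter tames per-pixel speckle in the projections before
    thresholding; the mask is then cleaned by opening and small-component
    removal.
    """
    same_grid(skull_retardation_proj.pixels.shape, skull_intensity_proj.pixels.shape)
    ret = skull_retardation_proj.pixels
    inten = skull_intensity_proj.pixels
    if median_width > 1:
        ret = ndimage.median_filter(np.nan_to_num(ret, nan=90.0), size=median_width, mode="nearest")
        inten = ndimage.median_filter(np.nan_to_num(inten, nan=-np.inf), size=median_width, mode="nearest")
    ok = np.isfinite(skull_retardation_proj.pixels) & np.isfinite(skull_intensity_proj.pixels)
    mask = ok & (ret <= ret_threshold_deg) & (inten >= int_threshold_db)
    if opening_width > 1:
        mask = ndimage.binary_opening(mask, structure=np.ones((opening_width, opening_width), bool))
    if min_area > 1:
        mask = _drop_small_2d(mask, min_area)
    return SutureMap(
        suture_mask=mask,
        source={
            "ret_threshold_deg": float(ret_threshold_deg),
            "int_threshold_db": float(int_threshold_db),
            "opening_width": int(opening_width),
        },
    )


def colocalize(
    calls: ChannelCallSet, sutures: SutureMap, dilation_px: int = 2
) -> tuple[ChannelCallSet, float | None]:
    """Fill ``inside_suture`` per component; return the inside fraction.

    A component is inside if its centroid falls on the suture mask dilated by
    the stated margin.  An empty call set reports ``None`` (no-data).
    """
    same_grid(calls.channel_mask.shape, sutures.suture_mask.shape)
    dil = sutures.suture_mask
    if dilation_px > 0:
        dil = ndimage.binary_dilation(dil, structure=morphology.disk(dilation_px))
    for comp in calls.components:
        cx = int(round(comp.centroid_xy[0]))
        cy = int(round(comp.centroid_xy[1]))
        cx = min(max(cx, 0), dil.shape[0] - 1)
        cy = min(max(cy, 0), dil.shape[1] - 1)
        comp.inside_suture = bool(dil[cx, cy])
    if not calls.components:
        return calls, None
    frac = sum(c.inside_suture for c in calls.components) / len(calls.components)
    return calls, float(frac)


def band_max_projection(
    vol: DerivedVolume, band: str, b: BoundarySet, max_thickness_px: int | None = None
) -> np.ndarray:
    """Peak value per column within a named boundary band (NaN outside).

    ``max_thickness_px`` clips the band depth below its upper boundary --
    used to keep deep, noise-dominated voxels out of flow binarization.
    """
    from .projections import band_bounds, _band_rows

    nz = vol.shape[0]
    lo, hi, ok = band_bounds(b, nz, band)
    r_lo, r_hi = _band_rows(lo, hi, nz)
    if max_thickness_px is not None:
        r_hi = np.minimum(r_hi, r_lo + int(max_thickness_px))
    zz = np.arange(nz)[:, None, None]
    in_band = (zz >= r_lo[None]) & (zz < r_hi[None]) & ok[None]
    vals = np.where(in_band, vol.values, -np.inf).max(axis=0)
    return np.where(np.isfinite(vals), vals, np.nan)


def calibrate_flow_threshold(static_enface: np.ndarray, quantile: float = 0.99) -> float:
    """Flow threshold = the stated quantile of a vessel-free projection."""
    vals = np.asarray(static_enface, float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ConfigError("no finite pixels to calibrate the flow threshold from")
    return float(np.quantile(vals, quantile))


def tbi_metrics(
    octa_series: list[tuple[float, DerivedVolume]],
    roi: tuple[int, int, int, int],
    flow_threshold: float,
    boundaries: BoundarySet | None = None,
    band: str = "brain",
    band_thickness_px: int | None = 40,
) -> list[VesselMetrics]:
    """Vessel density and avascular area inside an ROI over a time series.

    Each angiogram is projected en-face as the peak decorrelation over the
    named band (max projection: a thin vessel should count regardless of the
    band thickness), binarized at ``flow_threshold`` inside the half-open ROI
    ``(x0, x1, y0, y1)``.  ``avascular_area_px`` is the largest connected
    below-threshold component (the wound core), not the total
    below-threshold area.
    """
    times = [t for t, _ in octa_series]
    if times != sorted(times):
        raise ConfigError("octa_series must be sorted by timepoint")
    out: list[VesselMetrics] = []
    for t, vol in octa_series:
        _, nx, ny = vol.shape
        x0, x1, y0, y1 = roi
        if not (0 <= x0 < x1 <= nx and 0 <= y0 < y1 <= ny):
            raise ConfigError("ROI outside grid")
        if boundaries is not None:
            enface = band_max_projection(vol, band, boundaries, max_thickness_px=band_thickness_px)
        else:
            enface = vol.values.max(axis=0)
        patch = np.nan_to_num(enface[x0:x1, y0:y1], nan=0.0)
        vascular = patch >= flow_threshold
        density = float(vascular.mean())
        labels = measure.label(~vascular, connectivity=1)
        if labels.max() > 0:
            avascular = int(max(r.area for r in measure.regionprops(labels)))
        else:
            avascular = 0
        out.append(
            VesselMetrics(timepoint=float(t), roi=tuple(roi), vessel_density=density, avascular_area_px=avascular)
        )
    return out
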