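"""Threshold-mask organ segmentation of the layered cranium.

Six steps, run per B-scan:

1. intensity and DOPU contrast volumes (from :mod:`mfoct.signals`);
2. threshold selection (intensity threshold for the Air-Skin pick, a second
   lower intensity cutoff for the deep skull, and a DOPU threshold selecting
   depolarizing tissue);
3. mask generation from the thresholds;
4. DOPU-Intensity mask = product of the two masks, followed by a lateral
   morphological opening that removes laterally narrow pigment-spot blobs
   while preserving the skull plate;
5. edge picking: top of the intensity mask = Air-Skin boundary; top/bottom of
   the cleaned DOPU-Intensity mask = Skin-Skull / Skull-Brain boundaries;
6. per-B-scan smoothing-spline fit of each boundary, followed by a
   cross-B-scan median filter for en-face stability.

Threshold values are configuration (the method sets but never prints them);
defaults are derived from the per-volume noise floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field
from scipy import interpolate, ndimage

from .core import DerivedVolume, FormatError, same_grid

__all__ = [
    "SegmentationParams",
    "BoundarySet",
    "make_masks",
    "combine_masks",
    "open_mask",
    "extract_boundaries",
    "smooth_boundaries",
    "layer_masks",
    "segment_volume",
]


class SegmentationParams(BaseModel):
    """Thresholds and smoothing knobs for the six-step segmentation."""

    thr_int_air_skin_db: float = 8.0  # offset above the noise floor, dB
    thr_int_skull_brain_db: float = 10.0  # lower cutoff for the deep skull, dB
    thr_dopu: float = Field(default=0.70, gt=0, lt=1)
    opening_width: int = Field(default=21, ge=1)  # lateral voxels
    spline_smoothing: float = Field(default=0.5, ge=0)  # RMS residual budget, voxels
    min_component_area: int = Field(default=30, ge=0)
    cross_bscan_median: int = Field(default=3, ge=1)
    thresholds_absolute: bool = False  # if True, thr_int_* are absolute dB


@dataclass
class BoundarySet:
    """Three depth surfaces per (x, y), fractional voxels, plus validity.

    ``z_midline`` is the mid-depth of the skull, the divider between the
    extra- and intracranial compartments.
    """

    z_air_skin: np.ndarray  # (nx, ny) float
    z_skin_skull: np.ndarray
    z_skull_brain: np.ndarray
    valid: np.ndarray  # (3, nx, ny) bool, ordered as the fields above

    @property
    def z_midline(self) -> np.ndarray:
        return 0.5 * (self.z_skin_skull + self.z_skull_brain)

    @property
    def midline_valid(self) -> np.ndarray:
        return self.valid[1] & self.valid[2]

    def check_ordering(self, tol: float = 1e-6) -> bool:
        ok = self.valid.all(axis=0)
        a, b, c = self.z_air_skin[ok], self.z_skin_skull[ok], self.z_skull_brain[ok]
        return bool(np.all(a <= b + tol) and np.all(b <= c + tol))


def _resolve_thresholds(
    intensity: DerivedVolume, p: SegmentationParams, air_rows: int = 8
) -> tuple[float, float]:
    if p.thresholds_absolute:
        return p.thr_int_air_skin_db, p.thr_int_skull_brain_db
    floor = float(np.median(intensity.values[: max(air_rows, 1)]))
    return floor + p.thr_int_air_skin_db, floor + p.thr_int_skull_brain_db


def make_masks(
    intensity: DerivedVolume, dopu: DerivedVolume, p: SegmentationParams
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold masks.

    ``intensity_mask``: voxels at/above the Air-Skin intensity threshold.
    ``dopu_mask``: depolarizing tissue -- DOPU at/below threshold, gated by
    the lower (Skull-Brain) intensity cutoff so that dark noise with random
    polarization does not enter the mask.
    """
    same_grid(intensity.shape, dopu.shape)
    if intensity.kind != "intensity_dB":
        raise FormatError("segmentation expects a dB intensity volume")
    thr_as, thr_sb = _resolve_thresholds(intensity, p)
    intensity_mask = intensity.values >= thr_as
    dopu_mask = (dopu.values <= p.thr_dopu) & (intensity.values >= thr_sb)
    return intensity_mask, dopu_mask


def combine_masks(intensity_mask: np.ndarray, dopu_mask: np.ndarray) -> np.ndarray:
    """DOPU-Intensity mask: elementwise boolean product."""
    same_grid(intensity_mask.shape, dopu_mask.shape)
    return intensity_mask & dopu_mask


def open_mask(dopu_intensity_mask: np.ndarray, p: SegmentationParams) -> np.ndarray:
    """Lateral morphological opening with a 1 x opening_width line element.

    Removes laterally narrow pigment-spot blobs; the wide skull plate
    survives.
    """
    if p.opening_width <= 1:
        return dopu_intensity_mask.copy()
    w = p.opening_width
    structure = np.ones((1, w, 1), dtype=bool)
    # edge-pad laterally so the opening does not erode the image borders
    padded = np.pad(dopu_intensity_mask, ((0, 0), (w, w), (0, 0)), mode="edge")
    opened = ndimage.binary_opening(padded, structure=structure)
    return opened[:, w:-w, :]


def _drop_small_components(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove per-B-scan connected components below min_area voxels."""
    out = np.empty_like(mask)
    structure = np.ones((3, 3), dtype=bool)
    for y in range(mask.shape[2]):
        labels, n = ndimage.label(mask[:, :, y], structure=structure)
        if n == 0:
            out[:, :, y] = False
            continue
        counts = np.bincount(labels.ravel())
        keep = counts >= min_area
        keep[0] = False
        out[:, :, y] = keep[labels]
    return out


def _first_last_true(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    any_true = mask.any(axis=0)
    first = mask.argmax(axis=0)
    last = mask.shape[0] - 1 - mask[::-1].argmax(axis=0)
    return first, last, any_true


def extract_boundaries(
    intensity_mask: np.ndarray, cleaned_mask: np.ndarray, min_component_area: int = 0
) -> BoundarySet:
    """Raw per-column edge picks.

    Air-Skin = first true row of the intensity mask; Skin-Skull = first true
    row of the cleaned DOPU-Intensity mask; Skull-Brain = one past its last
    true row (half-open band convention).  Speckle islands smaller than
    ``min_component_area`` are removed per B-scan before picking.
    """
    same_grid(intensity_mask.shape, cleaned_mask.shape)
    if min_component_area > 1:
        intensity_mask = _drop_small_components(intensity_mask, min_component_area)
        cleaned_mask = _drop_small_components(cleaned_mask, min_component_area)

    first_i, _, ok_i = _first_last_true(intensity_mask)
    first_c, last_c, ok_c = _first_last_true(cleaned_mask)
    z_as = np.where(ok_i, first_i, np.nan).astype(float)
    z_ss = np.where(ok_c, first_c, np.nan).astype(float)
    z_sb = np.where(ok_c, last_c + 1, np.nan).astype(float)
    valid = np.stack([ok_i, ok_c, ok_c])
    if not valid.any():
        warnings.warn("no boundary evidence anywhere; all columns invalid")
    return BoundarySet(z_air_skin=z_as, z_skin_skull=z_ss, z_skull_brain=z_sb, valid=valid)


def _spline_fit(x: np.ndarray, z: np.ndarray, x_eval: np.ndarray, s_total: float) -> np.ndarray:
    try:
        tck = interpolate.splrep(x, z, k=min(3, x.size - 1), s=s_total)
        return np.asarray(interpolate.splev(x_eval, tck), dtype=float)
    except Exception:  # ill-conditioned fit: fall back to linear interpolation
        return np.interp(x_eval, x, z)


def _smooth_one(z: np.ndarray, ok: np.ndarray, s_rms: float) -> tuple[np.ndarray, np.ndarray]:
    """Robust smoothing-spline fit of one boundary along one B-scan.

    Two passes: a heavily smoothed coarse fit flags columns whose residual
    exceeds 3 robust sigmas (speckle spikes), then the final spline with the
    configured RMS residual budget is fit on the inliers and evaluated at
    every column (interpolating invalid ones).
    """
    nx = z.shape[0]
    xi = np.flatnonzero(ok)
    if xi.size < 4:
        return z.copy(), ok.copy()
    x = np.arange(nx, dtype=float)
    coarse_rms = max(s_rms, 3.0)
    coarse = _spline_fit(x[xi], z[xi], x[xi], (coarse_rms**2) * xi.size)
    resid = z[xi] - coarse
    sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    thresh = max(3.0 * sigma, 2.0)
    inliers = xi[np.abs(resid) <= thresh]
    if inliers.size < 4:
        inliers = xi
    fitted = _spline_fit(x[inliers], z[inliers], x, (s_rms**2) * inliers.size)
    return fitted, np.ones(nx, dtype=bool)


def smooth_boundaries(raw: BoundarySet, p: SegmentationParams) -> BoundarySet:
    """Spline-smooth each boundary per B-scan and re-impose ordering.

    Invalid columns are interpolated from the fit; B-scans with fewer than 4
    valid columns stay invalid.  A cross-B-scan median filter stabilizes the
    en-face surfaces.  Ordering violations are clipped to the neighboring
    boundary.
    """
    zs = [raw.z_air_skin, raw.z_skin_skull, raw.z_skull_brain]
    nx, ny = zs[0].shape
    out_z = [np.array(z, dtype=float) for z in zs]
    out_v = raw.valid.copy()
    for b in range(3):
        for y in range(ny):
            fitted, ok = _smooth_one(out_z[b][:, y], raw.valid[b][:, y], p.spline_smoothing)
            out_z[b][:, y] = fitted
            out_v[b][:, y] = ok
    if p.cross_bscan_median > 1 and ny >= p.cross_bscan_median:
        for b in range(3):
            filled = np.where(out_v[b], out_z[b], np.nanmedian(out_z[b]))
            out_z[b] = ndimage.median_filter(
                filled, size=(1, p.cross_bscan_median), mode="nearest"
            )
    z_as, z_ss, z_sb = out_z
    z_ss = np.maximum(z_ss, z_as)
    z_sb = np.maximum(z_sb, z_ss)
    return BoundarySet(z_air_skin=z_as, z_skin_skull=z_ss, z_skull_brain=z_sb, valid=out_v)


def layer_masks(b: BoundarySet, nz: int) -> dict[str, np.ndarray]:
    """Half-open voxel bands: skin [as, ss), skull [ss, sb), brain [sb, nz).

    Fractional boundaries are rounded half-up.  Bands are mutually disjoint
    and their union is everything below the Air-Skin boundary (in valid
    columns).
    """
    r_as = np.floor(b.z_air_skin + 0.5)
    r_ss = np.floor(b.z_skin_skull + 0.5)
    r_sb = np.floor(b.z_skull_brain + 0.5)
    zz = np.arange(nz)[:, None, None]
    ok = b.valid.all(axis=0)[None, :, :]
    skin = (zz >= r_as) & (zz < r_ss) & ok
    skull = (zz >= r_ss) & (zz < r_sb) & ok
    brain = (zz >= r_sb) & ok
    return {"skin": skin, "skull": skull, "brain": brain}


def segment_volume(
    intensity: DerivedVolume, dopu: DerivedVolume, p: SegmentationParams | None = None
) -> tuple[BoundarySet, dict[str, np.ndarray]]:
    """Run the full six-step pipeline; returns boundaries and layer masks."""
    p = p or SegmentationParams()
    imask, dmask = make_masks(intensity, dopu, p)
    combined = combine_masks(imask, dmask)
    cleaned = open_mask(combined, p)
    raw = extract_boundaries(imask, cleaned, min_component_area=p.min_component_area)
    smooth = smooth_boundaries(raw, p)
    return smooth, layer_masks(smooth, intensity.shape[0])
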