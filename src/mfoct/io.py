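"""Readers and writers for tomograms, derived volumes, and en-face images.

HDF5 is the canonical volume container (datasets ``/H`` and ``/V`` plus
acquisition attributes); paired multi-page TIFF (real/imag planes, order
recorded in the ImageDescription tag) is supported for interchange.  All
writers disable HDF5 object timestamps so identical data produce identical
files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import Acquisition, DerivedVolume, FormatError, PolTomogramSeries
from .projections import EnFaceImage
from .segmentation import BoundarySet

__all__ = [
    "write_tomogram",
    "read_tomogram",
    "write_volume",
    "read_volume",
    "write_boundaries",
    "read_boundaries",
    "boundaries_to_csv",
    "write_layer_masks",
    "write_enface_png",
    "write_enface_tiff",
    "write_json",
    "config_hash",
]

_ACQ_ATTRS = ("pitch_z_um", "pitch_x_um", "pitch_y_um", "wavelength_um", "n_repeats", "line_rate_hz")


def config_hash(payload: str | bytes | dict) -> str:
    """Stable SHA-256 of a JSON-serializable payload."""
    if isinstance(payload, dict):
        payload = json.dumps(payload, sort_keys=True)
    if isinstance(payload, str):
        payload = payload.encode("utf-8")
    return hashlib.sha256(payload).hexdigest()


def _acq_to_attrs(acq: Acquisition) -> dict:
    return {k: getattr(acq, k) for k in _ACQ_ATTRS}


def _acq_from_attrs(attrs) -> Acquisition:
    kwargs = {}
    for k in _ACQ_ATTRS:
        if k not in attrs:
            raise FormatError(f"missing acquisition attribute '{k}'")
        kwargs[k] = attrs[k]
    kwargs["n_repeats"] = int(kwargs["n_repeats"])
    return Acquisition(**kwargs)


def write_tomogram(path: str | Path, series: PolTomogramSeries, extra_attrs: dict | None = None) -> Path:
    """Write a tomogram series to HDF5 (``.h5``) or paired TIFF (``.tif``)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w", track_order=True) as f:
            for name, arr in (("H", series.h), ("V", series.v)):
                f.create_dataset(name, data=arr, track_times=False)
            for k, v in _acq_to_attrs(series.acquisition).items():
                f.attrs[k] = v
            for k, v in (extra_attrs or {}).items():
                f.attrs[k] = v
        return path
    if path.suffix.lower() in (".tif", ".tiff"):
        return write_tomogram_tiff(path, series)
    raise FormatError(f"unsupported tomogram container '{path.suffix}'")


def write_tomogram_tiff(
    path: str | Path, series: PolTomogramSeries, plane_order: str = "real_imag"
) -> Path:
    """Paired multi-page float TIFF: one file per channel, pages alternating
    real/imag planes in the order named by the metadata tag."""
    path = Path(path)
    if plane_order not in ("real_imag", "imag_real"):
        raise FormatError(f"unknown plane_order '{plane_order}'")
    n, nz, nx, ny = series.h.shape
    meta = {
        "format": "mfoct-tomogram",
        "plane_order": plane_order,
        "shape": [n, nz, nx, ny],
        "acquisition": _acq_to_attrs(series.acquisition),
    }
    for name, arr in (("H", series.h), ("V", series.v)):
        planes = [np.real(arr), np.imag(arr)]
        if plane_order == "imag_real":
            planes = planes[::-1]
        stack = np.stack(planes, axis=2).astype(np.float32)  # (n, nz, 2, nx, ny)
        out = path.with_name(f"{path.stem}_{name}{path.suffix}")
        tifffile.imwrite(out, stack.reshape(-1, nx, ny), description=json.dumps(meta))
    return path


def _read_tomogram_tiff(path: Path) -> PolTomogramSeries:
    arrays = {}
    meta = None
    for name in ("H", "V"):
        f = path.with_name(f"{path.stem}_{name}{path.suffix}")
        if not f.exists():
            raise FormatError(f"missing channel '{name}' file: {f.name}")
        with tifffile.TiffFile(f) as tf:
            desc = tf.pages[0].description
            data = tf.asarray()
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError as e:
            raise FormatError(f"channel '{name}': unreadable metadata tag") from e
        n, nz, nx, ny = meta["shape"]
        if data.shape != (n * nz * 2, nx, ny):
            raise FormatError(f"channel '{name}': page count disagrees with metadata shape")
        stack = data.reshape(n, nz, 2, nx, ny)
        if meta.get("plane_order", "real_imag") == "imag_real":
            imag, real = stack[:, :, 0], stack[:, :, 1]
        else:
            real, imag = stack[:, :, 0], stack[:, :, 1]
        arrays[name] = (real + 1j * imag).astype(np.complex64)
    acq = _acq_from_attrs(meta["acquisition"])
    if acq.n_repeats != arrays["H"].shape[0]:
        raise FormatError("n_repeats attribute disagrees with the page count")
    return PolTomogramSeries(h=arrays["H"], v=arrays["V"], acquisition=acq)


def read_tomogram(path: str | Path) -> PolTomogramSeries:
    """Read and validate a tomogram series (HDF5 or paired TIFF)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_tomogram_tiff(path)
    if path.suffix.lower() not in (".h5", ".hdf5"):
        raise FormatError(f"unsupported tomogram container '{path.suffix}'")
    with h5py.File(path, "r") as f:
        for name in ("H", "V"):
            if name not in f:
                raise FormatError(f"missing channel '{name}' in {path.name}")
        h = f["H"][()]
        v = f["V"][()]
        acq = _acq_from_attrs(f.attrs)
    if acq.n_repeats != h.shape[0]:
        raise FormatError("n_repeats attribute disagrees with dataset shape")
    return PolTomogramSeries(h=h, v=v, acquisition=acq)


def write_volume(path: str | Path, vol: DerivedVolume, extra_attrs: dict | None = None) -> Path:
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=vol.values.astype(np.float32), track_times=False)
            if vol.valid is not None:
                f.create_dataset("valid", data=vol.valid.astype(np.uint8), track_times=False)
            f.attrs["kind"] = vol.kind
            f.attrs["pitch_um"] = list(vol.pitch_um)
            for k, v in (extra_attrs or {}).items():
                f.attrs[k] = v
        return path
    if path.suffix.lower() in (".tif", ".tiff"):
        meta = {"format": "mfoct-volume", "kind": vol.kind, "pitch_um": list(vol.pitch_um)}
        meta.update(extra_attrs or {})
        tifffile.imwrite(path, vol.values.astype(np.float32), description=json.dumps(meta))
        return path
    raise FormatError(f"unsupported volume container '{path.suffix}'")


def read_volume(path: str | Path) -> DerivedVolume:
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "values" not in f:
                raise FormatError(f"missing dataset 'values' in {path.name}")
            values = f["values"][()]
            valid = f["valid"][()].astype(bool) if "valid" in f else None
            kind = f.attrs.get("kind")
            pitch = tuple(f.attrs.get("pitch_um", (3.4, 8.0, 8.0)))
        if kind is None:
            raise FormatError(f"missing attribute 'kind' in {path.name}")
        return DerivedVolume(values=values, kind=str(kind), pitch_um=pitch, valid=valid)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            meta = json.loads(tf.pages[0].description)
            values = tf.asarray()
        return DerivedVolume(values=values, kind=meta["kind"], pitch_um=tuple(meta["pitch_um"]))
    raise FormatError(f"unsupported volume container '{path.suffix}'")


def write_boundaries(path: str | Path, b: BoundarySet, extra_attrs: dict | None = None) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name, arr in (
            ("z_air_skin", b.z_air_skin),
            ("z_skin_skull", b.z_skin_skull),
            ("z_skull_brain", b.z_skull_brain),
        ):
            f.create_dataset(name, data=np.asarray(arr, np.float64), track_times=False)
        f.create_dataset("valid", data=b.valid.astype(np.uint8), track_times=False)
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v
    return path


def read_boundaries(path: str | Path) -> BoundarySet:
    with h5py.File(path, "r") as f:
        for name in ("z_air_skin", "z_skin_skull", "z_skull_brain", "valid"):
            if name not in f:
                raise FormatError(f"missing dataset '{name}' in boundary file")
        return BoundarySet(
            z_air_skin=f["z_air_skin"][()],
            z_skin_skull=f["z_skin_skull"][()],
            z_skull_brain=f["z_skull_brain"][()],
            valid=f["valid"][()].astype(bool),
        )


def boundaries_to_csv(path: str | Path, b: BoundarySet) -> Path:
    """Long-format CSV: one row per (B-scan y, column x)."""
    nx, ny = b.z_air_skin.shape
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    df = pd.DataFrame(
        {
            "bscan_y": yy.ravel(),
            "column_x": xx.ravel(),
            "z_air_skin": b.z_air_skin.ravel(),
            "z_skin_skull": b.z_skin_skull.ravel(),
            "z_skull_brain": b.z_skull_brain.ravel(),
            "valid_air_skin": b.valid[0].ravel(),
            "valid_skin_skull": b.valid[1].ravel(),
            "valid_skull_brain": b.valid[2].ravel(),
        }
    )
    df.to_csv(path, index=False)
    return Path(path)


def write_layer_masks(path: str | Path, masks: dict[str, np.ndarray]) -> Path:
    """uint8 multi-page TIFF, one page set per layer, order in the tag."""
    names = list(masks)
    stack = np.concatenate([masks[n].astype(np.uint8) for n in names], axis=0)
    tifffile.imwrite(Path(path), stack, description=json.dumps({"layers": names}))
    return Path(path)


def write_enface_png(path: str | Path, img: EnFaceImage) -> Path:
    """8-bit sRGB export; scalar images are min-max scaled, NaN renders black."""
    px = img.pixels
    if img.is_rgb:
        arr = np.nan_to_num(px, nan=0.0)
    else:
        finite = px[np.isfinite(px)]
        lo = float(finite.min()) if finite.size else 0.0
        hi = float(finite.max()) if finite.size else 1.0
        span = (hi - lo) or 1.0
        arr = np.nan_to_num((px - lo) / span, nan=0.0)
    arr8 = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr8)
    return Path(path)


def write_enface_tiff(path: str | Path, img: EnFaceImage) -> Path:
    meta = {"format": "mfoct-enface", "kind": img.kind, "layer_tag": img.layer_tag, "units": img.units}
    tifffile.imwrite(Path(path), img.pixels.astype(np.float32), description=json.dumps(meta))
    return Path(path)


def write_json(path: str | Path, obj) -> Path:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
    return Path(path)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")
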