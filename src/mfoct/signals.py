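"""PS-OCT contrast volumes: intensity, accumulative retardation, DOPU.

All three operate on a dual-channel complex tomogram series and return
:class:`~mfoct.core.DerivedVolume` objects on the same grid.  Contrast
volumes average over repeats; angiography (see :mod:`mfoct.angiography`)
consumes the repeats separately.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .core import ConfigError, DerivedVolume, PolTomogramSeries

__all__ = [
    "compute_intensity",
    "estimate_noise_floor_db",
    "compute_retardation",
    "compute_dopu",
]

DB_FLOOR = -80.0  # dB value assigned to exactly-zero voxels


def _linear_intensity(tomo: PolTomogramSeries, repeat_policy: str) -> np.ndarray:
    i = np.abs(tomo.h) ** 2 + np.abs(tomo.v) ** 2
    if repeat_policy == "mean":
        return i.mean(axis=0)
    if repeat_policy == "first":
        return i[0]
    raise ConfigError(f"unknown repeat_policy '{repeat_policy}'")


def compute_intensity(
    tomo: PolTomogramSeries,
    repeat_policy: str = "mean",
    scale: str = "dB",
    air_rows: int = 8,
) -> DerivedVolume:
    """Per-voxel intensity ``I = |H|^2 + |V|^2``.

    In dB scale the reference is the median power of the top ``air_rows``
    rows (a noise-floor estimate); exactly-zero voxels map to ``DB_FLOOR``.
    """
    lin = _linear_intensity(tomo, repeat_policy).astype(np.float32)
    pitch = tomo.acquisition.pitch_um
    if scale == "linear":
        return DerivedVolume(values=lin, kind="intensity_linear", pitch_um=pitch)
    if scale != "dB":
        raise ConfigError(f"unknown scale '{scale}'")
    ref = float(np.median(lin[: max(air_rows, 1)]))
    if ref <= 0.0:
        nz_vals = lin[lin > 0]
        if nz_vals.size == 0:
            warnings.warn("all-zero volume: dB undefined, returning floor")
            return DerivedVolume(values=np.full_like(lin, DB_FLOOR), kind="intensity_dB", pitch_um=pitch)
        ref = float(nz_vals.mean()) * 1e-8
        warnings.warn("zero noise floor in air rows; using a tiny synthetic reference")
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(lin / ref)
    db = np.where(lin > 0, db, DB_FLOOR).astype(np.float32)
    return DerivedVolume(values=db, kind="intensity_dB", pitch_um=pitch)


def estimate_noise_floor_db(intensity_db: DerivedVolume, air_rows: int = 8) -> float:
    """Median dB of the top air rows (0 by construction when noise present)."""
    return float(np.median(intensity_db.values[: max(air_rows, 1)]))


def compute_retardation(tomo: PolTomogramSeries) -> DerivedVolume:
    """Accumulative retardation ``delta = arctan(|V| / |H|)`` in [0, 90] deg.

    Computed per repeat, then averaged.  Voxels with ``|H| = |V| = 0`` are 0
    and flagged invalid.
    """
    ah = np.abs(tomo.h)
    av = np.abs(tomo.v)
    delta = np.degrees(np.arctan2(av, ah)).mean(axis=0).astype(np.float32)
    valid = ((ah + av) > 0).all(axis=0)
    delta = np.where(valid, delta, 0.0).astype(np.float32)
    vol = DerivedVolume(
        values=delta, kind="retardation_deg", pitch_um=tomo.acquisition.pitch_um, valid=valid
    )
    vol.check_bounds()
    return vol


def _stokes_normalized(h: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, ...]:
    s0 = np.abs(h) ** 2 + np.abs(v) ** 2
    hv = h * np.conj(v)
    q = np.abs(h) ** 2 - np.abs(v) ** 2
    u = 2.0 * hv.real
    w = -2.0 * hv.imag
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(s0 > 0, 1.0 / s0, 0.0)
    return s0, q * inv, u * inv, w * inv


def compute_dopu(
    tomo: PolTomogramSeries,
    kernel: tuple[int, int] = (5, 5),
    intensity_weighted: bool = False,
) -> DerivedVolume:
    """Degree of polarization uniformity via Stokes-vector averaging.

    Per voxel, the normalized Stokes vector ``(q, u, v)`` is computed from
    the channel amplitudes; DOPU is the Euclidean norm of its mean over a
    ``(kz, kx)`` window inside each B-scan (and over repeats), clipped to
    [0, 1].  With ``intensity_weighted`` the raw Stokes components are
    averaged before normalization instead.
    """
    kz, kx = kernel
    if kz < 1 or kx < 1 or kz % 2 == 0 or kx % 2 == 0:
        raise ConfigError("DOPU kernel sizes must be odd and >= 1")
    nz, nx, _ = tomo.shape
    if kz > nz or kx > nx:
        raise ConfigError("DOPU kernel larger than the B-scan")

    s0, q, u, w = _stokes_normalized(tomo.h, tomo.v)
    if intensity_weighted:
        q, u, w = (
            np.where(s0 > 0, comp * s0, 0.0) for comp in (q, u, w)
        )
    size = (kz, kx, 1)

    def win(a: np.ndarray) -> np.ndarray:
        return ndimage.uniform_filter(a.mean(axis=0), size=size, mode="nearest")

    qm, um, wm = win(q), win(u), win(w)
    if intensity_weighted:
        s0m = win(s0)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = np.where(s0m > 0, 1.0 / s0m, 0.0)
        qm, um, wm = qm * inv, um * inv, wm * inv
    dopu = np.sqrt(qm**2 + um**2 + wm**2)
    dopu = np.clip(dopu, 0.0, 1.0).astype(np.float32)
    vol = DerivedVolume(values=dopu, kind="dopu", pitch_um=tomo.acquisition.pitch_um)
    vol.check_bounds()
    return vol
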