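"""Split-spectrum amplitude-decorrelation angiography (SSADA).

The tomogram is already in the depth domain, so each A-scan's complex depth
profile is inverse-transformed to a synthetic spectrum, multiplied by M
Gaussian sub-band windows, and transformed back.  Decorrelation between
consecutive repeats is then averaged over the sub-bands:

    D = 1 - (1 / (M (N-1))) sum_m sum_n  A_mn A_m,n+1 / (A_mn^2/2 + A_m,n+1^2/2)

Polarization channels are combined as ``sqrt(|H|^2 + |V|^2)`` before the
decorrelation, i.e. angiography runs on the polarization-summed amplitude of
the same acquisition that feeds the PS-OCT contrasts.

Defaults (M = 4 bands, 50% overlap, Gaussian windows) are declared stand-ins:
the source acquisition protocol does not state them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigError, DerivedVolume, PolTomogramSeries

__all__ = ["SplitSpectrumSet", "split_spectrum", "ssada_decorrelation"]


@dataclass
class SplitSpectrumSet:
    """Per-band, per-repeat amplitude volumes, axes (band, repeat, z, x, y)."""

    amplitudes: np.ndarray
    band_centers: np.ndarray  # spectral bin of each window center
    band_sigmas: np.ndarray  # Gaussian sigma in spectral bins (inf = flat)
    pitch_um: tuple[float, float, float] = (3.4, 8.0, 8.0)

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes)
        if a.ndim != 5:
            raise ConfigError("amplitudes must be 5-D (band, repeat, z, x, y)")
        if a.shape[0] < 1:
            raise ConfigError("at least one spectral band is required")
        if np.any(a < 0):
            raise ConfigError("band amplitudes must be non-negative")
        self.amplitudes = a

    @property
    def n_bands(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.amplitudes.shape[1]


def band_windows(nz: int, m: int, overlap: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian window stack (m, nz) with equally spaced centers.

    Window FWHMs tile the spectral axis so that adjacent windows share the
    stated overlap fraction.  ``m == 1`` returns a flat (all-ones) window so
    the split is the identity.
    """
    if m < 1:
        raise ConfigError("band count must be >= 1")
    if m > nz // 4:
        raise ConfigError(f"band count {m} too large for {nz} spectral samples (bands degenerate)")
    if not 0.0 <= overlap < 1.0:
        raise ConfigError("overlap fraction must be in [0, 1)")
    if m == 1:
        return np.ones((1, nz)), np.array([nz / 2.0]), np.array([np.inf])
    fwhm = nz / (1.0 + (m - 1) * (1.0 - overlap))
    step = fwhm * (1.0 - overlap)
    centers = fwhm / 2.0 + step * np.arange(m)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    k = np.arange(nz)
    win = np.exp(-0.5 * ((k[None, :] - centers[:, None]) / sigma) ** 2)
    return win, centers, np.full(m, sigma)


def split_spectrum(
    tomo: PolTomogramSeries, m: int = 4, overlap: float = 0.5, dtype=np.float64
) -> SplitSpectrumSet:
    """Band-filtered combined-channel amplitudes for every repeat."""
    nz = tomo.shape[0]
    win, centers, sigmas = band_windows(nz, m, overlap)
    n = tomo.n_repeats
    out = np.empty((m, n) + tomo.shape, dtype=dtype)
    for i in range(n):
        spec_h = np.fft.ifft(tomo.h[i].astype(np.complex128), axis=0)  # (k, x, y)
        spec_v = np.fft.ifft(tomo.v[i].astype(np.complex128), axis=0)
        for b in range(m):
            w = win[b][:, None, None]
            p = np.abs(np.fft.fft(spec_h * w, axis=0)) ** 2
            p += np.abs(np.fft.fft(spec_v * w, axis=0)) ** 2
            out[b, i] = np.sqrt(p)
    return SplitSpectrumSet(
        amplitudes=out, band_centers=centers, band_sigmas=sigmas, pitch_um=tomo.acquisition.pitch_um
    )


def ssada_decorrelation(
    bands: SplitSpectrumSet,
    intensity_db: DerivedVolume | None = None,
    floor_db: float | None = None,
) -> DerivedVolume:
    """Amplitude decorrelation averaged over bands and repeat pairs.

    Voxels whose mean intensity is below ``floor_db`` are masked to 0: pure
    noise decorrelates fully and must not masquerade as flow.  A voxel where
    both frames are exactly zero contributes a correlation term of 1
    (identical zeros).
    """
    if bands.n_repeats < 2:
        raise ConfigError("SSADA needs >= 2 repeats per B-scan position")
    a = bands.amplitudes.astype(np.float64)
    a1 = a[:, :-1]
    a2 = a[:, 1:]
    num = a1 * a2
    den = 0.5 * (a1**2 + a2**2)
    corr = np.ones_like(num)
    np.divide(num, den, out=corr, where=den > 0)
    d = 1.0 - corr.mean(axis=(0, 1))
    d = np.clip(d, 0.0, 1.0).astype(np.float32)
    if intensity_db is not None and floor_db is not None:
        if intensity_db.shape != d.shape:
            raise ConfigError("intensity volume grid does not match the band grid")
        d = np.where(intensity_db.values >= floor_db, d, 0.0).astype(np.float32)
    vol = DerivedVolume(values=d, kind="decorrelation", pitch_um=bands.pitch_um)
    vol.check_bounds()
    return vol
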