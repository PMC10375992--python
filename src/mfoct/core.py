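"""Core data containers and shared utilities.

The whole pipeline works on three kinds of arrays:

* dual-channel complex tomogram series (``PolTomogramSeries``) with axes
  ``(repeat, z, x, y)`` per channel, z index 0 being the shallowest (air-side)
  row;
* real-valued per-voxel contrast maps (``DerivedVolume``): linear/dB
  intensity, accumulative retardation in degrees, DOPU, or SSADA
  decorrelation;
* 2-D en-face images (defined in :mod:`mfoct.projections`).

All randomness in the package flows through :func:`substream`, which derives
an independent, reproducible generator from a single integer seed and a stage
label.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Acquisition",
    "PolTomogramSeries",
    "DerivedVolume",
    "VOLUME_KINDS",
    "substream",
    "ConfigError",
    "FormatError",
    "StageError",
    "GeometryError",
]


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


class FormatError(ValueError):
    """Malformed or inconsistent input file (CLI exit code 3)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 4)."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


class GeometryError(ConfigError):
    """Scene geometry does not fit the requested grid."""


def substream(seed: int, label: str) -> np.random.Generator:
    """Return an independent generator for (seed, stage-label).

    Uses the CRC32 of the label as a spawn key so that every stage draws from
    its own substream of the single pipeline seed; re-running a single stage
    reproduces exactly the numbers it saw inside a full run.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


@dataclass(frozen=True)
class Acquisition:
    """Acquisition metadata attached to a tomogram series.

    Defaults follow the imaging-system description: ~3.4 um axial resolution,
    8 um transverse resolution, 25 kHz line rate.
    """

    pitch_z_um: float = 3.4
    pitch_x_um: float = 8.0
    pitch_y_um: float = 8.0
    wavelength_um: float = 1.3
    n_repeats: int = 4
    line_rate_hz: float = 25_000.0

    @property
    def pitch_um(self) -> tuple[float, float, float]:
        return (self.pitch_z_um, self.pitch_x_um, self.pitch_y_um)


VOLUME_KINDS = (
    "intensity_dB",
    "intensity_linear",
    "retardation_deg",
    "dopu",
    "decorrelation",
)


@dataclass
class PolTomogramSeries:
    """Dual-polarization-channel complex tomogram series.

    ``h`` and ``v`` have axes ``(repeat, z, x, y)`` and identical shapes.
    """

    h: np.ndarray
    v: np.ndarray
    acquisition: Acquisition

    def __post_init__(self) -> None:
        h, v = np.asarray(self.h), np.asarray(self.v)
        if h.ndim != 4 or v.ndim != 4:
            raise FormatError("channels H and V must be 4-D (repeat, z, x, y)")
        if h.shape != v.shape:
            raise FormatError(f"channel shape mismatch: H {h.shape} vs V {v.shape}")
        if h.shape[0] < 1:
            raise FormatError("at least one repeat is required")
        for name, arr in (("H", h), ("V", v)):
            if not np.iscomplexobj(arr):
                raise FormatError(f"channel {name} must be complex-valued")
            if not (np.all(np.isfinite(arr.real)) and np.all(np.isfinite(arr.imag))):
                raise FormatError(f"channel {name} contains NaN/Inf")
        self.h, self.v = h, v

    @property
    def n_repeats(self) -> int:
        return self.h.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """Grid shape (nz, nx, ny)."""
        return self.h.shape[1:]

    def require_repeats(self, n: int) -> None:
        if self.n_repeats < n:
            raise ConfigError(
                f"operation requires >= {n} repeats per B-scan position, got {self.n_repeats}"
            )


_KIND_BOUNDS = {
    "dopu": (0.0, 1.0),
    "retardation_deg": (0.0, 90.0),
    "decorrelation": (0.0, 1.0),
    "intensity_linear": (0.0, np.inf),
}


@dataclass
class DerivedVolume:
    """Real scalar contrast volume on the tomogram grid, axes (z, x, y)."""

    values: np.ndarray
    kind: str
    pitch_um: tuple[float, float, float] = (3.4, 8.0, 8.0)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise FormatError("DerivedVolume values must be 3-D (z, x, y)")
        if self.kind not in VOLUME_KINDS:
            raise FormatError(f"unknown volume kind '{self.kind}'")
        self.values = values

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def check_bounds(self) -> None:
        """Raise if values leave the range their kind allows."""
        bounds = _KIND_BOUNDS.get(self.kind)
        if bounds is None:
            return
        lo, hi = bounds
        v = self.values
        if v.size and (np.nanmin(v) < lo - 1e-6 or np.nanmax(v) > hi + 1e-6):
            raise ValueError(f"{self.kind} values outside [{lo}, {hi}]")


def same_grid(*shapes: tuple[int, ...]) -> None:
    """Raise :class:`FormatError` unless all shapes agree."""
    first = shapes[0]
    for s in shapes[1:]:
        if s != first:
            raise FormatError(f"grid mismatch: {first} vs {s}")
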