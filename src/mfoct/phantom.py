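"""Synthetic polarization-resolved OCT phantom of a layered cranium.

The phantom stands in for real acquisitions: a three-layer cranium
(skin / skull / brain) under air, with

* smooth, band-limited boundary surfaces (Air-Skin, Skin-Skull, Skull-Brain);
* pigment spots at the bottom of the skin and a pigmented sheet at the skull
  base (high backscatter, depolarizing);
* a birefringent skull plate with non-birefringent, high-backscatter suture
  gaps (a cross plus two lateral disks);
* fully developed speckle (per-voxel circular complex Gaussian fields);
* static tissue that reuses one speckle realization across repeats, and
  vessels that redraw speckle independently per repeat (full flow
  decorrelation);
* transcranial vessels routed through suture columns only, with an optional
  control vessel planted outside the sutures.

Forward polarization model: with circularly polarized illumination the
detected channels of a non-depolarizing voxel are ``H = c * cos(d)`` and
``V = i * c * sin(d)`` where ``c`` is the speckle field and ``d`` the
accumulated single-pass retardation ``(360/lambda0) * dn * 2 * depth``
(degrees) through the birefringent skull.  Depolarizing voxels (pigment, and
a per-voxel random fraction of the scattering skull) instead emit a random
polarization state drawn uniformly on the Poincare sphere, which is the
simplest mechanism that yields a low DOPU after spatial averaging while
preserving per-voxel intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field
from scipy import ndimage

from .core import Acquisition, GeometryError, ConfigError, PolTomogramSeries, substream

__all__ = [
    "LayerOptics",
    "SutureConfig",
    "PigmentConfig",
    "VesselConfig",
    "SceneConfig",
    "Vessel",
    "ChannelTruth",
    "PhantomScene",
    "PhantomGroundTruth",
    "build_scene",
    "render_series",
    "rasterize_vessels",
    "dn_for_retardation",
    "build_tbi_scene",
    "make_tbi_series",
]


class LayerOptics(BaseModel):
    """Optical properties of one tissue layer."""

    backscatter: float = Field(gt=0)
    attenuation_per_um: float = Field(ge=0)
    birefringence_dn: float = Field(ge=0)
    depol_fraction: float = Field(ge=0, le=1, default=0.0)


class SutureConfig(BaseModel):
    enabled: bool = True
    backscatter: float = 4.0
    depol_fraction: float = 0.45
    cross_width_px: int = 4
    disk_radius_px: int = 5


class PigmentConfig(BaseModel):
    n_spots: int = 12
    spot_radius_px: tuple[float, float] = (2.0, 4.0)
    min_spot_separation_px: float = 24.0  # keeps spot runs narrower than the opening element
    spot_thickness_px: int = 4
    base_sheet: bool = True
    sheet_thickness_px: int = 3
    backscatter: float = 10.0


class VesselConfig(BaseModel):
    n_skin: int = 5
    n_intracranial: int = 5
    n_transcranial: int = 3
    radius_skin_um: float = 12.0
    radius_intracranial_um: float = 16.0
    radius_transcranial_um: float = 10.0
    skin_depth_offset_px: float = 5.0
    intra_depth_offset_px: float = 6.0
    transcranial_overhang_px: float = 6.0
    min_anchor_separation_px: float = 14.0
    control_channel_outside_suture: bool = False


def dn_for_retardation(delta_deg: float, thickness_um: float, wavelength_um: float = 1.3) -> float:
    """Birefringence giving ``delta_deg`` accumulated single-pass retardation
    at the bottom of a layer of the given thickness."""
    return delta_deg * wavelength_um / (360.0 * 2.0 * thickness_um)


class SceneConfig(BaseModel):
    """Full parameter set for :func:`build_scene`."""

    grid_shape: tuple[int, int, int] = (256, 192, 96)  # (nz, nx, ny)
    pitch_um: tuple[float, float, float] = (3.4, 8.0, 8.0)
    depth_air_skin: float = 20.0
    depth_skin_skull: float = 44.0
    depth_skull_brain: float = 92.0
    undulation_amplitude: float = 3.0
    undulation_sigma: float = 10.0
    skin: LayerOptics = LayerOptics(
        backscatter=1.0, attenuation_per_um=0.0015, birefringence_dn=0.0, depol_fraction=0.0
    )
    skull: LayerOptics = LayerOptics(
        backscatter=2.0, attenuation_per_um=0.002, birefringence_dn=3.319e-4, depol_fraction=0.8
    )
    brain: LayerOptics = LayerOptics(
        backscatter=0.3, attenuation_per_um=0.003, birefringence_dn=0.0, depol_fraction=0.0
    )
    suture: SutureConfig = SutureConfig()
    pigment: PigmentConfig = PigmentConfig()
    vessels: VesselConfig = VesselConfig()
    wavelength_um: float = 1.3

    def check_geometry(self) -> "SceneConfig":
        """Raise :class:`GeometryError` unless the layers fit the grid."""
        nz, nx, ny = self.grid_shape
        if nz <= 0 or nx <= 0 or ny <= 0:
            raise GeometryError("grid_shape must be positive")
        amp = self.undulation_amplitude
        if amp < 0:
            raise GeometryError("undulation_amplitude must be >= 0")
        if self.depth_air_skin - amp < 1:
            raise GeometryError("air gap too small for the requested undulation")
        if self.depth_skin_skull - self.depth_air_skin < 2 * amp + 2:
            raise GeometryError("skin layer does not fit the grid/undulation")
        if self.depth_skull_brain - self.depth_skin_skull < 2 * amp + 2:
            raise GeometryError("skull layer does not fit the grid/undulation")
        margin = self.vessels.intra_depth_offset_px + 4
        if nz - self.depth_skull_brain - amp < margin:
            raise GeometryError("brain layer does not fit below the skull")
        return self


@dataclass
class Vessel:
    """Tube segment: centerline polyline in voxel coords (z, x, y)."""

    points: np.ndarray  # (k, 3) float
    radius_um: float
    tag: str  # skin | intracranial | transcranial


@dataclass
class ChannelTruth:
    """Routing-log entry for a vessel crossing the skull."""

    anchor_xy: tuple[int, int]
    vessel_index: int
    in_suture: bool


@dataclass
class PhantomScene:
    config: SceneConfig
    seed: int
    z_air_skin: np.ndarray  # (nx, ny) float
    z_skin_skull: np.ndarray
    z_skull_brain: np.ndarray
    suture_mask: np.ndarray  # (nx, ny) bool
    pigment_mask: np.ndarray  # (nz, nx, ny) bool
    vessels: list[Vessel] = field(default_factory=list)
    channel_truth: list[ChannelTruth] = field(default_factory=list)
    extra_flow_mask: np.ndarray | None = None  # (nz, nx, ny) bool

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.config.grid_shape)


@dataclass
class PhantomGroundTruth:
    z_air_skin: np.ndarray
    z_skin_skull: np.ndarray
    z_skull_brain: np.ndarray
    pigment_mask: np.ndarray
    suture_mask: np.ndarray
    vessel_masks: dict[str, np.ndarray]  # tag -> (nz, nx, ny) bool
    flow_mask: np.ndarray  # union of all flow voxels
    channel_truth: list[ChannelTruth]
    rng_seed: int


def _round_half_up(z: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(z) + 0.5).astype(int)


def _smooth_surface(rng: np.random.Generator, shape, offset, amplitude, sigma) -> np.ndarray:
    if amplitude == 0:
        return np.full(shape, float(offset))
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    f = (f - f.mean()) / max(f.std(), 1e-12)
    return offset + amplitude * f


def _build_suture_mask(cfg: SceneConfig) -> np.ndarray:
    _, nx, ny = cfg.grid_shape
    mask = np.zeros((nx, ny), dtype=bool)
    if not cfg.suture.enabled:
        return mask
    w = cfg.suture.cross_width_px
    cx, cy = nx // 2, ny // 2
    mask[cx - w // 2 : cx - w // 2 + w, :] = True
    mask[:, cy - w // 2 : cy - w // 2 + w] = True
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r = cfg.suture.disk_radius_px
    for dx in (-nx // 4, nx // 4):
        mask |= (xx - (cx + dx)) ** 2 + (yy - cy) ** 2 <= r**2
    return mask


def build_scene(config: SceneConfig, seed: int) -> PhantomScene:
    """Deterministically build a phantom scene from (config, seed)."""
    cfg = config
    cfg.check_geometry()
    nz, nx, ny = cfg.grid_shape
    rng = substream(seed, "scene")

    z_as = _smooth_surface(rng, (nx, ny), cfg.depth_air_skin, cfg.undulation_amplitude, cfg.undulation_sigma)
    z_ss = _smooth_surface(rng, (nx, ny), cfg.depth_skin_skull, cfg.undulation_amplitude, cfg.undulation_sigma)
    z_sb = _smooth_surface(rng, (nx, ny), cfg.depth_skull_brain, cfg.undulation_amplitude, cfg.undulation_sigma)
    # geometry validation guarantees ordering; clip defensively
    z_ss = np.maximum(z_ss, z_as + 1.0)
    z_sb = np.maximum(z_sb, z_ss + 1.0)

    suture_mask = _build_suture_mask(cfg)
    r_as, r_ss, r_sb = _round_half_up(z_as), _round_half_up(z_ss), _round_half_up(z_sb)

    pigment = np.zeros((nz, nx, ny), dtype=bool)
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    rmax = cfg.pigment.spot_radius_px[1]
    m = int(np.ceil(rmax)) + 2
    sep2 = cfg.pigment.min_spot_separation_px**2
    centers: list[tuple[int, int]] = []
    attempts = 0
    if nx - m <= m or ny - m <= m:  # grid too thin for spots
        attempts = 60 * max(cfg.pigment.n_spots, 1)
    while len(centers) < cfg.pigment.n_spots and attempts < 60 * max(cfg.pigment.n_spots, 1):
        attempts += 1
        cx = int(rng.integers(m, nx - m))
        cy = int(rng.integers(m, ny - m))
        if all((cx - ax) ** 2 + (cy - ay) ** 2 >= sep2 for ax, ay in centers):
            centers.append((cx, cy))
    for cx, cy in centers:
        r = rng.uniform(*cfg.pigment.spot_radius_px)
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        for px, py in np.argwhere(disk):
            z1 = r_ss[px, py]
            z0 = max(r_as[px, py], z1 - cfg.pigment.spot_thickness_px)
            pigment[z0:z1, px, py] = True
    if cfg.pigment.base_sheet:
        t = cfg.pigment.sheet_thickness_px
        for px in range(nx):
            for py in range(ny):
                z1 = r_sb[px, py]
                z0 = max(r_ss[px, py], z1 - t)
                pigment[z0:z1, px, py] = True

    vessels: list[Vessel] = []
    channel_truth: list[ChannelTruth] = []
    vc = cfg.vessels
    xs = np.arange(0, nx, 4, dtype=float)
    if xs[-1] != nx - 1:
        xs = np.append(xs, nx - 1.0)
    # lateral vessels run along x at distinct, well-separated y positions, so
    # skin and intracranial vessels never stack en-face: their projections
    # overlap only where a transcranial vessel crosses the skull
    n_lat = vc.n_skin + vc.n_intracranial
    ys: list[int] = []
    if n_lat > 0:
        cand = rng.permutation(np.arange(2, max(3, ny - 2)))
        for y0 in cand:
            if all(abs(int(y0) - y) >= 4 for y in ys):
                ys.append(int(y0))
            if len(ys) == n_lat:
                break
        if len(ys) < n_lat:
            raise GeometryError("grid too small to place the requested lateral vessels")
    for i in range(vc.n_skin):
        y0 = float(ys[i])
        zline = z_ss[xs.astype(int), int(y0)] - vc.skin_depth_offset_px
        pts = np.column_stack([zline, xs, np.full_like(xs, y0)])
        vessels.append(Vessel(points=pts, radius_um=vc.radius_skin_um, tag="skin"))
    for i in range(vc.n_intracranial):
        y0 = float(ys[vc.n_skin + i])
        zline = z_sb[xs.astype(int), int(y0)] + vc.intra_depth_offset_px
        pts = np.column_stack([zline, xs, np.full_like(xs, y0)])
        vessels.append(Vessel(points=pts, radius_um=vc.radius_intracranial_um, tag="intracranial"))

    if vc.n_transcranial > 0:
        margin = 4
        cand = np.argwhere(suture_mask)
        cand = cand[
            (cand[:, 0] >= margin) & (cand[:, 0] < nx - margin)
            & (cand[:, 1] >= margin) & (cand[:, 1] < ny - margin)
        ]
        if len(cand) == 0:
            raise GeometryError("no suture columns available for transcranial vessels")
        cand = cand[rng.permutation(len(cand))]
        anchors: list[tuple[int, int]] = []
        for px, py in cand:
            if all((px - ax) ** 2 + (py - ay) ** 2 >= vc.min_anchor_separation_px**2 for ax, ay in anchors):
                anchors.append((int(px), int(py)))
            if len(anchors) == vc.n_transcranial:
                break
        if len(anchors) < vc.n_transcranial:
            raise GeometryError("could not place the requested transcranial vessels inside sutures")
        for ax, ay in anchors:
            z0 = z_ss[ax, ay] - vc.transcranial_overhang_px
            z1 = z_sb[ax, ay] + vc.transcranial_overhang_px
            zs = np.linspace(z0, z1, max(int(z1 - z0) // 3, 2))
            pts = np.column_stack([zs, np.full_like(zs, float(ax)), np.full_like(zs, float(ay))])
            vessels.append(Vessel(points=pts, radius_um=vc.radius_transcranial_um, tag="transcranial"))
            channel_truth.append(ChannelTruth(anchor_xy=(ax, ay), vessel_index=len(vessels) - 1, in_suture=True))

    if vc.control_channel_outside_suture:
        dist = ndimage.distance_transform_edt(~suture_mask)
        margin = 6
        ok = dist >= 8
        ok[:margin, :] = ok[-margin:, :] = False
        ok[:, :margin] = ok[:, -margin:] = False
        cand = np.argwhere(ok)
        if len(cand) == 0:
            raise GeometryError("no plate columns available for the control channel")
        px, py = cand[rng.integers(len(cand))]
        z0 = z_ss[px, py] - vc.transcranial_overhang_px
        z1 = z_sb[px, py] + vc.transcranial_overhang_px
        zs = np.linspace(z0, z1, max(int(z1 - z0) // 3, 2))
        pts = np.column_stack([zs, np.full_like(zs, float(px)), np.full_like(zs, float(py))])
        vessels.append(Vessel(points=pts, radius_um=vc.radius_transcranial_um, tag="transcranial"))
        channel_truth.append(
            ChannelTruth(anchor_xy=(int(px), int(py)), vessel_index=len(vessels) - 1, in_suture=False)
        )

    for v in vessels:
        if np.any(v.points[:, 0] < 0) or np.any(v.points[:, 0] > nz - 1):
            raise GeometryError("vessel tube exits the grid axially")

    return PhantomScene(
        config=cfg,
        seed=seed,
        z_air_skin=z_as,
        z_skin_skull=z_ss,
        z_skull_brain=z_sb,
        suture_mask=suture_mask,
        pigment_mask=pigment,
        vessels=vessels,
        channel_truth=channel_truth,
    )


def rasterize_vessels(scene: PhantomScene) -> dict[str, np.ndarray]:
    """Voxelize vessel tubes; returns per-tag boolean masks on the grid."""
    nz, nx, ny = scene.grid_shape
    pz, px_, py_ = scene.config.pitch_um
    masks = {tag: np.zeros((nz, nx, ny), dtype=bool) for tag in ("skin", "intracranial", "transcranial")}
    for v in scene.vessels:
        mask = masks[v.tag]
        pts = v.points
        # densify the polyline to <=1 voxel steps
        dense = [pts[0]]
        for a, b in zip(pts[:-1], pts[1:]):
            n = max(int(np.ceil(np.abs(b - a).max())), 1)
            for t in np.linspace(0, 1, n + 1)[1:]:
                dense.append(a + t * (b - a))
        rz = v.radius_um / pz
        rx = v.radius_um / px_
        ry = v.radius_um / py_
        bz, bx, by = int(np.ceil(rz)), int(np.ceil(rx)), int(np.ceil(ry))
        for z0, x0, y0 in dense:
            zl, zh = max(int(z0) - bz, 0), min(int(z0) + bz + 2, nz)
            xl, xh = max(int(x0) - bx, 0), min(int(x0) + bx + 2, nx)
            yl, yh = max(int(y0) - by, 0), min(int(y0) + by + 2, ny)
            if zl >= zh or xl >= xh or yl >= yh:
                continue
            zz, xx, yy = np.meshgrid(
                np.arange(zl, zh), np.arange(xl, xh), np.arange(yl, yh), indexing="ij"
            )
            d2 = (
                ((zz - z0) * pz) ** 2 + ((xx - x0) * px_) ** 2 + ((yy - y0) * py_) ** 2
            )
            mask[zl:zh, xl:xh, yl:yh] |= d2 <= v.radius_um**2
    return masks


def render_series(
    scene: PhantomScene,
    acq: Acquisition | None = None,
    snr_db: float | None = 25.0,
    seed: int = 0,
    n_repeats: int | None = None,
) -> tuple[PolTomogramSeries, PhantomGroundTruth]:
    """Render a tomogram series plus ground truth from a scene.

    ``snr_db`` is the per-voxel SNR of the skin-layer surface backscatter over
    the additive detector noise; ``None`` renders noise-free.
    """
    cfg = scene.config
    nz, nx, ny = scene.grid_shape
    if acq is None:
        acq = Acquisition(
            pitch_z_um=cfg.pitch_um[0],
            pitch_x_um=cfg.pitch_um[1],
            pitch_y_um=cfg.pitch_um[2],
            wavelength_um=cfg.wavelength_um,
        )
    if (acq.pitch_z_um, acq.pitch_x_um, acq.pitch_y_um) != tuple(cfg.pitch_um):
        raise ConfigError("acquisition pitch disagrees with the scene grid")
    n = int(n_repeats if n_repeats is not None else acq.n_repeats)
    if n < 1:
        raise ConfigError("n_repeats must be >= 1")
    if snr_db is not None and not np.isfinite(snr_db):
        raise ConfigError("SNR must be finite (or None for noise-free)")

    rng = substream(seed, "render")
    r_as = _round_half_up(scene.z_air_skin)
    r_ss = _round_half_up(scene.z_skin_skull)
    r_sb = _round_half_up(scene.z_skull_brain)
    zz = np.arange(nz)[:, None, None]
    lab = (zz >= r_as).astype(np.int8) + (zz >= r_ss) + (zz >= r_sb)  # 0 air..3 brain

    def lut(vals):
        return np.asarray(vals, dtype=np.float32)[lab]

    bs = lut([0.0, cfg.skin.backscatter, cfg.skull.backscatter, cfg.brain.backscatter])
    att = lut(
        [0.0, cfg.skin.attenuation_per_um, cfg.skull.attenuation_per_um, cfg.brain.attenuation_per_um]
    )
    depol = lut([0.0, cfg.skin.depol_fraction, cfg.skull.depol_fraction, cfg.brain.depol_fraction])

    in_suture_col = scene.suture_mask[None, :, :] & (lab == 2)
    if cfg.suture.enabled:
        bs = np.where(in_suture_col, cfg.suture.backscatter, bs)
        depol = np.where(in_suture_col, cfg.suture.depol_fraction, depol)
    bs = np.where(scene.pigment_mask, cfg.pigment.backscatter, bs)
    depol = np.where(scene.pigment_mask, 1.0, depol)

    att_vox = att * acq.pitch_z_um
    optical_depth = np.cumsum(att_vox, axis=0) - att_vox  # path to the voxel top
    mu = (bs * np.exp(-2.0 * optical_depth)).astype(np.float32)

    # accumulative single-pass retardation, degrees
    coeff = 360.0 / cfg.wavelength_um * 2.0 * cfg.skull.birefringence_dn  # deg per um depth
    depth_in_skull = np.clip(zz - r_ss + 1, 0, np.maximum(r_sb - r_ss, 0)) * acq.pitch_z_um
    delta_deg = np.where(scene.suture_mask[None, :, :], 0.0, coeff * depth_in_skull)
    delta = np.deg2rad(delta_deg).astype(np.float32)

    f_h = np.cos(delta).astype(np.complex64)
    f_v = (1j * np.sin(delta)).astype(np.complex64)
    scr = rng.random(size=(nz, nx, ny)) < depol
    k = int(scr.sum())
    if k:
        u = rng.random(k)
        beta = rng.uniform(0.0, 2 * np.pi, k)
        f_h[scr] = np.sqrt(1.0 - u)
        f_v[scr] = np.sqrt(u) * np.exp(1j * beta)

    sigma = np.sqrt(mu / 2.0).astype(np.float32)

    def speckle(shape):
        return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)).astype(np.complex64)

    c0 = sigma * speckle((nz, nx, ny))

    vessel_masks = rasterize_vessels(scene)
    flow = np.zeros((nz, nx, ny), dtype=bool)
    for m in vessel_masks.values():
        flow |= m
    if scene.extra_flow_mask is not None:
        flow |= scene.extra_flow_mask
    nflow = int(flow.sum())
    sig_flow = sigma[flow]

    h = np.empty((n, nz, nx, ny), dtype=np.complex64)
    v = np.empty((n, nz, nx, ny), dtype=np.complex64)
    for i in range(n):
        ci = c0
        if nflow:
            ci = c0.copy()
            ci[flow] = sig_flow * speckle((nflow,))
        h[i] = ci * f_h
        v[i] = ci * f_v

    if snr_db is not None:
        noise_pow = cfg.skin.backscatter * 10.0 ** (-snr_db / 10.0)
        ns = np.float32(np.sqrt(noise_pow / 2.0))
        h += ns * speckle(h.shape)
        v += ns * speckle(v.shape)

    acq = Acquisition(
        pitch_z_um=acq.pitch_z_um,
        pitch_x_um=acq.pitch_x_um,
        pitch_y_um=acq.pitch_y_um,
        wavelength_um=acq.wavelength_um,
        n_repeats=n,
        line_rate_hz=acq.line_rate_hz,
    )
    series = PolTomogramSeries(h=h, v=v, acquisition=acq)
    truth = PhantomGroundTruth(
        z_air_skin=scene.z_air_skin.copy(),
        z_skin_skull=scene.z_skin_skull.copy(),
        z_skull_brain=scene.z_skull_brain.copy(),
        pigment_mask=scene.pigment_mask.copy(),
        suture_mask=scene.suture_mask.copy(),
        vessel_masks=vessel_masks,
        flow_mask=flow,
        channel_truth=list(scene.channel_truth),
        rng_seed=seed,
    )
    return series, truth


def build_tbi_scene(
    config: SceneConfig,
    fraction: float,
    roi: tuple[int, int, int, int],
    seed: int,
    depth_range_px: tuple[int, int] = (6, 16),
) -> tuple[PhantomScene, np.ndarray]:
    """Scene with an injury-like flow region covering an exact en-face
    fraction of the ROI (half-open ``(x0, x1, y0, y1)``) in the brain layer.

    Returns the scene and the true en-face flow-column mask.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError("fraction must be in [0, 1]")
    vessel_free = config.model_copy(
        update={"vessels": VesselConfig(n_skin=0, n_intracranial=0, n_transcranial=0)}
    )
    scene = build_scene(vessel_free, seed)
    nz, nx, ny = scene.grid_shape
    x0, x1, y0, y1 = roi
    if not (0 <= x0 < x1 <= nx and 0 <= y0 < y1 <= ny):
        raise ConfigError("ROI outside grid")
    rng = substream(seed, "tbi-flow")
    fld = ndimage.gaussian_filter(rng.standard_normal((nx, ny)), 3.0, mode="wrap")
    roi_vals = fld[x0:x1, y0:y1]
    k = int(round(fraction * roi_vals.size))
    colmask = np.zeros((nx, ny), dtype=bool)
    if k > 0:
        thr = np.sort(roi_vals.ravel())[-k]
        sel = roi_vals >= thr
        # exact count: break ties deterministically
        if sel.sum() > k:
            flat = np.argsort(roi_vals.ravel())[::-1][:k]
            sel = np.zeros(roi_vals.size, dtype=bool)
            sel[flat] = True
            sel = sel.reshape(roi_vals.shape)
        colmask[x0:x1, y0:y1] = sel
    r_sb = _round_half_up(scene.z_skull_brain)
    zz = np.arange(nz)[:, None, None]
    d0, d1 = depth_range_px
    band = (zz >= r_sb + d0) & (zz < r_sb + d1)
    scene.extra_flow_mask = band & colmask[None, :, :]
    return scene, colmask


def make_tbi_series(
    config: SceneConfig,
    fractions: list[float],
    roi: tuple[int, int, int, int],
    seed: int,
    timepoints_h: list[float] | None = None,
) -> list[tuple[float, PhantomScene, np.ndarray]]:
    """Injury time series: nested flow regions of increasing coverage.

    All timepoints share geometry and the same underlying random field, so
    coverage grows monotonically, mimicking revascularization.
    """
    if timepoints_h is None:
        timepoints_h = [0.5, 24.0, 48.0][: len(fractions)]
        while len(timepoints_h) < len(fractions):
            timepoints_h.append(timepoints_h[-1] + 24.0)
    out = []
    for t, f in zip(timepoints_h, fractions):
        scene, colmask = build_tbi_scene(config, f, roi, seed)
        out.append((t, scene, colmask))
    return out
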