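"""Six-step threshold-mask segmentation."""

import numpy as np
import pytest

from mfoct import phantom, pipeline, signals
from mfoct.core import DerivedVolume, FormatError
from mfoct.phantom import LayerOptics, PigmentConfig, SceneConfig, SutureConfig, VesselConfig
from mfoct.segmentation import (
    BoundarySet,
    SegmentationParams,
    combine_masks,
    extract_boundaries,
    layer_masks,
    make_masks,
    open_mask,
    segment_volume,
    smooth_boundaries,
)

from conftest import boundary_rmse, layer_accuracy, quiet_optics, small_scene_config


def vol(values, kind="intensity_dB"):
    return DerivedVolume(values=np.asarray(values, np.float32), kind=kind)


def abs_params(**kw):
    base = dict(thresholds_absolute=True, thr_int_air_skin_db=10.0, thr_int_skull_brain_db=5.0)
    base.update(kw)
    return SegmentationParams(**base)


class TestMasks:
    def test_uniform_below_threshold_all_false(self):
        p = abs_params()
        i = vol(np.zeros((8, 6, 2)))
        d = vol(np.ones((8, 6, 2)), kind="dopu")
        imask, dmask = make_masks(i, d, p)
        assert not imask.any() and not dmask.any()

    def test_mismatched_grids_rejected(self):
        with pytest.raises(FormatError):
            make_masks(vol(np.zeros((8, 6, 2))), vol(np.ones((8, 6, 3)), kind="dopu"), abs_params())

    def test_combine_identity_and_disjoint(self):
        rng = np.random.default_rng(0)
        m = rng.random((6, 5, 2)) > 0.5
        np.testing.assert_array_equal(combine_masks(m, np.ones_like(m)), m)
        assert not combine_masks(m, ~m).any()

    def test_combine_equals_bruteforce_tile(self):
        rng = np.random.default_rng(1)
        a = rng.random((16, 16, 1)) > 0.4
        b = rng.random((16, 16, 1)) > 0.6
        got = combine_masks(a, b)
        expect = np.zeros_like(a)
        for z in range(16):
            for x in range(16):
                expect[z, x, 0] = bool(a[z, x, 0]) and bool(b[z, x, 0])
        np.testing.assert_array_equal(got, expect)

    def test_intensity_mask_matches_tissue_noise_free(self, quiet_render):
        _, _, series, truth = quiet_render
        i = signals.compute_intensity(series)
        d = signals.compute_dopu(series, kernel=(1, 9))
        imask, _ = make_masks(i, d, SegmentationParams())
        zz = np.arange(series.shape[0])[:, None, None]
        tissue = zz >= np.floor(truth.z_air_skin + 0.5).astype(int)
        jacc = (imask & tissue).sum() / (imask | tissue).sum()
        assert jacc >= 0.99

    def test_dopu_mask_selects_skull_and_pigment(self):
        # strongly depolarizing skull: per-voxel holes are phantom properties,
        # not mask-logic defects, so use depol ~1 for the Jaccard check
        cfg = small_scene_config(
            skin=LayerOptics(backscatter=1.0, attenuation_per_um=0.001, birefringence_dn=0.0),
            skull=LayerOptics(backscatter=2.0, attenuation_per_um=0.001,
                              birefringence_dn=3.3e-4, depol_fraction=0.95),
            brain=LayerOptics(backscatter=0.3, attenuation_per_um=0.0005, birefringence_dn=0.0),
            suture=SutureConfig(enabled=False),
            undulation_amplitude=1.0,
            vessels=VesselConfig(n_skin=0, n_intracranial=0, n_transcranial=0),
        )
        scene = phantom.build_scene(cfg, seed=71)
        series, truth = phantom.render_series(scene, snr_db=25.0, seed=71, n_repeats=1)
        i = signals.compute_intensity(series)
        d = signals.compute_dopu(series, kernel=(1, 9))
        _, dmask = make_masks(i, d, SegmentationParams())
        zz = np.arange(i.shape[0])[:, None, None]
        r_ss = np.floor(truth.z_skin_skull + 0.5).astype(int)
        r_sb = np.floor(truth.z_skull_brain + 0.5).astype(int)
        target = ((zz >= r_ss) & (zz < r_sb)) | truth.pigment_mask
        jacc = (dmask & target).sum() / (dmask | target).sum()
        assert jacc >= 0.9


class TestOpening:
    def test_thin_blob_removed(self):
        p = SegmentationParams(opening_width=7)
        m = np.zeros((8, 32, 1), bool)
        m[3, 10:13, 0] = True  # 3 voxels wide < 7
        assert not open_mask(m, p).any()

    def test_full_width_band_unchanged(self):
        p = SegmentationParams(opening_width=7)
        m = np.zeros((8, 32, 1), bool)
        m[3:5, :, 0] = True
        np.testing.assert_array_equal(open_mask(m, p), m)

    def test_phantom_pigment_spots_removed(self):
        # flat surfaces: spot rows never share a z-row with the skull plate,
        # so the lateral opening must remove every spot voxel
        cfg = small_scene_config(
            vessels=VesselConfig(n_skin=0, n_intracranial=0, n_transcranial=0),
            pigment=PigmentConfig(n_spots=6, base_sheet=True),
            undulation_amplitude=0.0,
        )
        scene = phantom.build_scene(cfg, seed=21)
        series, truth = phantom.render_series(scene, snr_db=25.0, seed=21, n_repeats=1)
        i = signals.compute_intensity(series)
        d = signals.compute_dopu(series, kernel=(1, 9))
        p = SegmentationParams()
        imask, dmask = make_masks(i, d, p)
        cleaned = open_mask(combine_masks(imask, dmask), p)
        zz = np.arange(series.shape[0])[:, None, None]
        r_ss = np.floor(truth.z_skin_skull + 0.5).astype(int)
        spots = truth.pigment_mask & (zz < r_ss)  # skin spots, not the base sheet
        assert spots.sum() > 0
        assert (cleaned & spots).sum() == 0


class TestExtract:
    def test_direct_readoff(self):
        i = np.zeros((64, 4, 1), bool)
        c = np.zeros_like(i)
        i[10:, :] = True
        c[20:40, :] = True  # half-open rows [20, 40)
        b = extract_boundaries(i, c)
        assert np.all(b.z_air_skin == 10)
        assert np.all(b.z_skin_skull == 20)
        assert np.all(b.z_skull_brain == 40)
        assert b.valid.all()

    def test_empty_column_invalid(self):
        i = np.zeros((16, 3, 1), bool)
        c = np.zeros_like(i)
        i[5:, :2] = True
        c[8:10, :2] = True
        with pytest.warns(UserWarning) if not i.any() else _nullcontext():
            b = extract_boundaries(i, c)
        assert not b.valid[0][2, 0]
        assert not b.valid[1][2, 0]
        assert np.isnan(b.z_air_skin[2, 0])

    def test_flat_phantom_exact_columns(self):
        opts = quiet_optics(
            skull=LayerOptics(backscatter=2.0, attenuation_per_um=0.0, birefringence_dn=0.0,
                              depol_fraction=1.0),
        )
        cfg = SceneConfig(grid_shape=(64, 48, 16), depth_air_skin=10, depth_skin_skull=20,
                          depth_skull_brain=40, **opts)
        scene = phantom.build_scene(cfg, seed=31)
        series, _ = phantom.render_series(scene, snr_db=None, seed=31, n_repeats=1)
        i = signals.compute_intensity(series)
        d = signals.compute_dopu(series, kernel=(1, 25))
        # noise-free uniform-state skin has DOPU exactly 1, so a high
        # threshold separates it sharply even at window-edge columns
        p = SegmentationParams(thr_dopu=0.9, opening_width=1, min_component_area=0)
        imask, dmask = make_masks(i, d, p)
        b = extract_boundaries(imask, combine_masks(imask, dmask))
        assert b.valid.all()
        assert np.all(b.z_air_skin == 10)
        assert np.all(b.z_skin_skull == 20)
        assert np.all(b.z_skull_brain == 40)


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *a):
        return False


class TestSmoothing:
    def test_flat_boundary_unchanged(self):
        flat = np.full((64, 4), 22.0)
        raw = BoundarySet(z_air_skin=flat.copy(), z_skin_skull=flat + 10,
                          z_skull_brain=flat + 30, valid=np.ones((3, 64, 4), bool))
        sm = smooth_boundaries(raw, SegmentationParams())
        np.testing.assert_allclose(sm.z_air_skin, 22.0, atol=0.1)

    def test_outlier_spike_rejected(self):
        flat = np.full((192, 1), 30.0)
        spiked = flat.copy()
        spiked[96, 0] += 15.0
        raw = BoundarySet(z_air_skin=spiked, z_skin_skull=flat + 10,
                          z_skull_brain=flat + 30, valid=np.ones((3, 192, 1), bool))
        sm = smooth_boundaries(raw, SegmentationParams(spline_smoothing=0.5))
        assert abs(sm.z_air_skin[96, 0] - 30.0) <= 1.0

    def test_invalid_columns_interpolated(self):
        z = np.full((64, 1), 15.0)
        valid = np.ones((3, 64, 1), bool)
        z2 = z.copy()
        z2[30:34] = np.nan
        valid[:, 30:34, 0] = False
        raw = BoundarySet(z_air_skin=z2, z_skin_skull=z + 10, z_skull_brain=z + 30, valid=valid)
        sm = smooth_boundaries(raw, SegmentationParams())
        assert np.all(np.isfinite(sm.z_air_skin))
        assert abs(sm.z_air_skin[31, 0] - 15.0) < 0.5

    def test_too_few_valid_columns_stay_invalid(self):
        z = np.full((64, 1), np.nan)
        valid = np.zeros((3, 64, 1), bool)
        z[5:7] = 12.0
        valid[:, 5:7, 0] = True
        raw = BoundarySet(z_air_skin=z, z_skin_skull=z + 5, z_skull_brain=z + 10, valid=valid)
        sm = smooth_boundaries(raw, SegmentationParams())
        assert not sm.valid[0].all()

    def test_sinusoidal_surface_recovery(self):
        opts = quiet_optics(
            skull=LayerOptics(backscatter=2.0, attenuation_per_um=0.002,
                              birefringence_dn=0.0, depol_fraction=0.95),
            pigment=PigmentConfig(n_spots=0, base_sheet=True),
        )
        cfg = SceneConfig(grid_shape=(128, 128, 16), depth_air_skin=20, depth_skin_skull=44,
                          depth_skull_brain=84, **opts)
        scene = phantom.build_scene(cfg, seed=41)
        x = np.arange(128, dtype=float)[:, None]
        wave = 5.0 * np.sin(2 * np.pi * x / 64.0)
        scene.z_air_skin = scene.z_air_skin + wave
        scene.z_skin_skull = scene.z_skin_skull + wave
        scene.z_skull_brain = scene.z_skull_brain + wave
        # rebuild the base sheet for the shifted surfaces
        r_ss = np.floor(scene.z_skin_skull + 0.5).astype(int)
        r_sb = np.floor(scene.z_skull_brain + 0.5).astype(int)
        pig = np.zeros(cfg.grid_shape, bool)
        for px in range(128):
            for py in range(16):
                z1 = r_sb[px, py]
                pig[max(r_ss[px, py], z1 - 3):z1, px, py] = True
        scene.pigment_mask = pig
        series, truth = phantom.render_series(scene, snr_db=25.0, seed=41, n_repeats=1)
        i = signals.compute_intensity(series)
        d = signals.compute_dopu(series, kernel=(3, 9))
        b, _ = segment_volume(i, d)
        rmse = boundary_rmse(b, truth)
        assert rmse["air_skin"] <= 1.5
        assert rmse["skin_skull"] <= 1.5
        assert rmse["skull_brain"] <= 1.5

    def test_ordering_reimposed(self):
        z = np.full((64, 1), 20.0)
        raw = BoundarySet(z_air_skin=z + 5, z_skin_skull=z, z_skull_brain=z + 1,
                          valid=np.ones((3, 64, 1), bool))
        sm = smooth_boundaries(raw, SegmentationParams())
        assert sm.check_ordering()


class TestLayerMasks:
    def test_thickness_arithmetic(self):
        b = BoundarySet(z_air_skin=np.full((4, 2), 10.0), z_skin_skull=np.full((4, 2), 20.0),
                        z_skull_brain=np.full((4, 2), 40.0), valid=np.ones((3, 4, 2), bool))
        masks = layer_masks(b, 64)
        assert masks["skin"][:, 0, 0].sum() == 10
        assert masks["skull"][:, 0, 0].sum() == 20
        assert masks["brain"][:, 0, 0].sum() == 24
        union = masks["skin"] | masks["skull"] | masks["brain"]
        assert union[:, 0, 0].sum() == 54  # everything below air
        assert not (masks["skin"] & masks["skull"]).any()

    def test_degenerate_skull_empty(self):
        b = BoundarySet(z_air_skin=np.full((2, 1), 5.0), z_skin_skull=np.full((2, 1), 20.0),
                        z_skull_brain=np.full((2, 1), 20.0), valid=np.ones((3, 2, 1), bool))
        masks = layer_masks(b, 32)
        assert masks["skull"].sum() == 0

    def test_phantom_label_accuracy(self, small_bundle):
        acc = layer_accuracy(small_bundle["boundaries"], small_bundle["truth"],
                             small_bundle["series"].shape[0])
        assert acc >= 0.98

    def test_midline_between_parents(self, small_bundle):
        b = small_bundle["boundaries"]
        ok = b.midline_valid & (b.z_skull_brain > b.z_skin_skull)
        mid = b.z_midline
        assert np.all(mid[ok] > b.z_skin_skull[ok])
        assert np.all(mid[ok] < b.z_skull_brain[ok])


class TestPipelineProperties:
    def test_deterministic(self, small_bundle):
        cfg = small_bundle["config"]
        b1, _ = pipeline.stage_segment(cfg, small_bundle["vols"])
        b2, _ = pipeline.stage_segment(cfg, small_bundle["vols"])
        assert b1.z_skin_skull.tobytes() == b2.z_skin_skull.tobytes()

    @pytest.mark.parametrize("seed", [51, 52, 53])
    def test_ordering_on_random_phantoms(self, seed):
        cfg = small_scene_config()
        scene = phantom.build_scene(cfg, seed=seed)
        series, _ = phantom.render_series(scene, snr_db=25.0, seed=seed, n_repeats=1)
        i = signals.compute_intensity(series)
        d = signals.compute_dopu(series, kernel=(1, 9))
        b, _ = segment_volume(i, d)
        assert b.check_ordering()

    def test_pigment_robustness_paired(self):
        deltas = []
        for seed in (61, 62):
            rmses = {}
            for spots in (True, False):
                cfg = small_scene_config(
                    pigment=PigmentConfig(n_spots=6 if spots else 0, base_sheet=True),
                    vessels=VesselConfig(n_skin=0, n_intracranial=0, n_transcranial=0),
                )
                scene = phantom.build_scene(cfg, seed=seed)
                series, truth = phantom.render_series(scene, snr_db=25.0, seed=seed, n_repeats=1)
                i = signals.compute_intensity(series)
                d = signals.compute_dopu(series, kernel=(1, 9))
                b, _ = segment_volume(i, d)
                rmses[spots] = boundary_rmse(b, truth)["skin_skull"]
            deltas.append(rmses[True] - rmses[False])
        assert float(np.mean(deltas)) <= 0.5
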