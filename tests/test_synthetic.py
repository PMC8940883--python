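"""Tests of the phantom builder and Beer-Lambert B-scan renderer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from octbrain.core import GeometryError, InvalidParameterError, TissueClass
from octbrain.frames import saturation_score
from octbrain.synthetic import (
    CLASS_MU_RANGES,
    AcquisitionSpec,
    DatasetSpec,
    PhantomSpec,
    axial_resolution,
    build_phantom,
    default_phantom_spec,
    expected_intensity,
    generate_dataset,
    inject_saturation,
    render_bscan,
    render_volume,
)


class TestAxialResolution:
    def test_simulated_system_rounds_to_8_um(self):
        # 1.31 um center wavelength, 100 nm FWHM bandwidth
        assert axial_resolution(1.31, 100) == pytest.approx(7.57, abs=0.005)
        assert round(axial_resolution(1.31, 100)) == 8

    def test_hand_evaluated_example(self):
        assert axial_resolution(1.00, 50) == pytest.approx(8.83, abs=0.005)

    @given(lc=st.floats(0.4, 2.0), bw=st.floats(10, 300))
    @settings(max_examples=25, derandomize=True)
    def test_doubling_bandwidth_halves_resolution(self, lc, bw):
        assert axial_resolution(lc, 2 * bw) == pytest.approx(
            axial_resolution(lc, bw) / 2, rel=1e-12)

    @pytest.mark.parametrize("args", [(0, 100), (1.31, 0), (-1, 100)])
    def test_non_positive_arguments_rejected(self, args):
        with pytest.raises(InvalidParameterError):
            axial_resolution(*args)


class TestBuildPhantom:
    def test_nor_phantom_is_laterally_constant_with_empty_mask(self, nor_phantom):
        assert not nor_phantom.inclusion_mask.any()
        tissue = nor_phantom.mu_map[nor_phantom.mu_map.max(axis=1) > 0]
        assert np.allclose(tissue, tissue[:, :1])

    def test_gbm_inclusion_component_count_matches_request(self):
        spec = PhantomSpec(TissueClass.GBM, 2.0, 0.4, n_inclusions=5,
                           inclusion_radius_range=(0.05, 0.15), seed=3)
        ph = build_phantom(spec, (256, 512))
        _, n = ndimage.label(ph.inclusion_mask)
        assert n == 5

    def test_same_spec_and_seed_reproduces_identical_phantom(self):
        spec = PhantomSpec(TissueClass.GBM, 2.5, 0.4, n_inclusions=3, seed=9)
        a = build_phantom(spec, (64, 128))
        b = build_phantom(spec, (64, 128))
        assert np.array_equal(a.mu_map, b.mu_map)
        assert np.array_equal(a.reflectivity_map, b.reflectivity_map)
        assert np.array_equal(a.inclusion_mask, b.inclusion_mask)

    def test_structureless_classes_reject_inclusions(self):
        with pytest.raises(InvalidParameterError):
            PhantomSpec(TissueClass.NOR, 2.0, n_inclusions=2)
        with pytest.raises(InvalidParameterError):
            PhantomSpec(TissueClass.PCNSL, 0.8, n_inclusions=1)

    def test_gbm_realized_lateral_amplitude_meets_spec(self):
        # the piecewise field must survive border smoothing: realized relative
        # spread of the lateral mu profile >= the requested variation amplitude
        rng = np.random.default_rng(7)
        for seed in rng.integers(0, 2**31, size=20):
            spec = default_phantom_spec(TissueClass.GBM, int(seed))
            ph = build_phantom(spec, (256, 512))
            row = ph.mu_map[30]  # shallow row, clear of inclusions
            assert (row.max() - row.min()) / row.mean() >= spec.mu_lateral_variation

    def test_class_separation_of_attenuation_ranges(self):
        # PCNSL mu range strictly below NOR's; GBM lateral variation exceeds NOR's
        assert CLASS_MU_RANGES[TissueClass.PCNSL][1] < CLASS_MU_RANGES[TissueClass.NOR][0]
        rng = np.random.default_rng(0)
        for seed in rng.integers(0, 2**31, size=5):
            gbm = build_phantom(default_phantom_spec(TissueClass.GBM, int(seed)), (64, 128))
            nor = build_phantom(default_phantom_spec(TissueClass.NOR, int(seed)), (64, 128))
            surface = gbm.mu_map.max(axis=1) > 0

            def lateral_rel_spread(ph):
                tissue = ph.mu_map[surface]
                return (tissue.max(axis=1) - tissue.min(axis=1)).max() / tissue.mean()

            assert lateral_rel_spread(gbm) > lateral_rel_spread(nor)
            pcnsl = build_phantom(default_phantom_spec(TissueClass.PCNSL, int(seed)),
                                  (64, 128))
            assert pcnsl.mu_map[surface].mean() < nor.mu_map[surface].mean()


class TestRenderBScan:
    def test_no_attenuation_no_noise_gives_constant_alines(self, tiny_acq):
        ph = build_phantom(PhantomSpec(TissueClass.NOR, 2.0, seed=1), (64, 128))
        ph.mu_map[:] = 0.0
        ph.reflectivity_map[:] = 1.0
        acq = AcquisitionSpec(n_depth_pixels=64, n_lateral_pixels=128,
                              speckle_shape=np.inf, noise_floor=0.0)
        frame = render_bscan(ph, acq, seed=0)
        assert np.allclose(frame.pixels, 1.0)

    @pytest.mark.parametrize("mu", [0.5, 1.0, 2.0, 4.0])
    def test_mean_log_aline_slope_recovers_attenuation(self, mu):
        # least-squares fit of depth-averaged log intensity vs. -2 mu dz
        spec = PhantomSpec(TissueClass.NOR, mu, seed=5)
        acq = AcquisitionSpec(n_lateral_pixels=1024, noise_floor=0.0)
        ph = build_phantom(spec, (256, 1024))
        frame = render_bscan(ph, acq, seed=6)
        dz = acq.pixel_pitch_axial
        surface = int(round(spec.surface_depth / dz))
        mean_log = np.log(frame.pixels[surface:]).mean(axis=1)
        slope = np.polyfit(np.arange(mean_log.size), mean_log, 1)[0]
        assert slope == pytest.approx(-2 * mu * dz, rel=0.05)

    def test_speckle_coefficient_of_variation_matches_gamma_shape(self):
        # CV = 1/sqrt(k) at fixed expected intensity
        for k in (1.0, 4.0):
            spec = PhantomSpec(TissueClass.NOR, 1.0, surface_depth=0.0, seed=2)
            ph = build_phantom(spec, (256, 512))
            ph.mu_map[:] = 0.0  # flat expectation so all pixels are one population
            acq = AcquisitionSpec(speckle_shape=k, noise_floor=0.0)
            frame = render_bscan(ph, acq, seed=3)
            cv = frame.pixels.std() / frame.pixels.mean()
            assert cv == pytest.approx(1 / np.sqrt(k), rel=0.05)

    def test_inclusions_are_darker_than_surrounding_tissue(self, gbm_phantom, tiny_acq):
        frame = render_bscan(gbm_phantom, tiny_acq, seed=4)
        mask = gbm_phantom.inclusion_mask
        rows = np.unique(np.nonzero(mask)[0])
        band = np.zeros_like(mask)
        band[rows] = True
        outside = band & ~mask
        assert frame.pixels[mask].mean() < frame.pixels[outside].mean()

    def test_geometry_mismatch_is_rejected(self, gbm_phantom):
        acq = AcquisitionSpec(n_depth_pixels=32, n_lateral_pixels=32)
        with pytest.raises(GeometryError):
            render_bscan(gbm_phantom, acq, seed=0)


class TestRenderVolume:
    def test_frame_count_and_metadata(self, gbm_phantom, tiny_acq):
        vol = render_volume(gbm_phantom, tiny_acq, n_frames=16, seed=8)
        assert vol.n_frames == 16
        assert vol.metadata.label == TissueClass.GBM
        assert vol.metadata.seed == 8

    def test_fewer_than_one_frame_rejected(self, gbm_phantom, tiny_acq):
        with pytest.raises(InvalidParameterError):
            render_volume(gbm_phantom, tiny_acq, n_frames=0, seed=0)

    @pytest.mark.parametrize("p,expect_all", [(0.0, False), (1.0, True)])
    def test_saturation_probability_drives_detector_flags(self, gbm_phantom, p,
                                                          expect_all):
        acq = AcquisitionSpec(n_depth_pixels=64, n_lateral_pixels=128,
                              saturation_probability=p)
        vol = render_volume(gbm_phantom, acq, n_frames=6, seed=9)
        flags = [saturation_score(vol.frame(k)) >= 0.02 for k in range(6)]
        assert all(flags) if expect_all else not any(flags)


class TestInjectSaturation:
    def test_empty_column_list_is_identity(self, small_volume):
        frame = small_volume.frame(0)
        out = inject_saturation(frame, [])
        assert np.array_equal(out.pixels, frame.pixels)

    def test_injected_column_mean_equals_max_intensity(self, small_volume):
        frame = small_volume.frame(0)
        out = inject_saturation(frame, [5])
        assert out.pixels[:, 5].mean() == out.pixels.max()

    def test_injection_raises_saturation_score(self, small_volume):
        frame = small_volume.frame(0)
        cols = list(range(0, 8))
        out = inject_saturation(frame, cols)
        assert saturation_score(out) > saturation_score(frame)

    def test_out_of_range_column_rejected(self, small_volume):
        with pytest.raises(IndexError):
            inject_saturation(small_volume.frame(0), [10**6])


class TestGenerateDataset:
    def test_manifest_counts_and_uniqueness(self, small_dataset):
        _, manifest, _ = small_dataset
        assert len(manifest) == 9
        assert manifest["volume_id"].is_unique
        counts = manifest["label"].value_counts()
        assert counts["NOR"] == 3 and counts["GBM"] == 3 and counts["PCNSL"] == 3
        assert (manifest["split_hint"] == "test").sum() == 3

    def test_regeneration_is_byte_identical(self, tmp_path):
        spec = DatasetSpec(train_volumes={"NOR": 1}, test_volumes={},
                           frames_per_volume=3,
                           acq=AcquisitionSpec(n_depth_pixels=32, n_lateral_pixels=64))
        m1 = generate_dataset(spec, tmp_path / "a", seed=5)
        m2 = generate_dataset(spec, tmp_path / "b", seed=5)
        p1 = (tmp_path / "a" / m1.iloc[0]["volume_id"]).with_suffix(".tif")
        p2 = (tmp_path / "b" / m2.iloc[0]["volume_id"]).with_suffix(".tif")
        assert p1.read_bytes() == p2.read_bytes()

    def test_study_scale_layout_yields_38_volumes(self, tmp_path):
        # 15/10/5 training + 2/3/3 holdout volumes, generated at toy raster size
        spec = DatasetSpec(
            frames_per_volume=1,
            acq=AcquisitionSpec(n_depth_pixels=16, n_lateral_pixels=32),
        )
        manifest = generate_dataset(spec, tmp_path, seed=1)
        assert len(manifest) == 38
        train = manifest[manifest["split_hint"] == "train"]["label"].value_counts()
        assert (train["NOR"], train["GBM"], train["PCNSL"]) == (15, 10, 5)
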