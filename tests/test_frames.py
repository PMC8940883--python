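"""Tests of volume IO and the despeckling / standardization pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octbrain.core import (
    BScanFrame,
    InsufficientFramesError,
    InvalidParameterError,
    MetadataError,
    OCTVolume,
    TissueClass,
    VolumeMetadata,
)
from octbrain.frames import (
    AugmentParams,
    augment,
    despeckle_stack,
    filter_frames,
    preprocess_volume,
    read_volume,
    register_translation,
    saturation_score,
    standardize,
    write_volume,
)
from octbrain.synthetic import AcquisitionSpec, inject_saturation, render_volume


class TestVolumeIO:
    def test_round_trip_preserves_pixels_and_metadata(self, small_volume, tmp_path):
        path = write_volume(small_volume, tmp_path / "v.tif")
        back = read_volume(path)
        assert np.array_equal(back.frames, small_volume.frames)
        assert back.metadata.label == small_volume.metadata.label
        assert back.metadata.pixel_pitch_axial == pytest.approx(
            small_volume.metadata.pixel_pitch_axial)

    def test_16bit_values_preserved_without_rescaling(self, tmp_path):
        frames = np.array([[[0, 1], [40000, 65535]]], dtype=np.uint16)
        vol = OCTVolume(frames, VolumeMetadata(volume_id="x", label=TissueClass.NOR,
                                               pixel_pitch_axial=1, pixel_pitch_lateral=1))
        path = write_volume(vol, tmp_path / "v.tif")
        back = read_volume(path)
        assert back.frames.dtype == np.uint16
        assert np.array_equal(back.frames, frames)

    def test_missing_sidecar_raises_metadata_error_naming_file(self, small_volume,
                                                               tmp_path):
        path = write_volume(small_volume, tmp_path / "v.tif")
        (tmp_path / "v.json").unlink()
        with pytest.raises(MetadataError, match="v.json"):
            read_volume(path)


class TestRegistration:
    def test_identical_frames_register_at_origin(self, small_volume):
        f = small_volume.frame(0)
        assert register_translation(f, f) == (0, 0)

    def test_known_circular_shift_is_recovered(self, small_volume):
        f = small_volume.frame(0)
        moved = f.with_pixels(np.roll(f.pixels, (3, -2), axis=(0, 1)))
        assert register_translation(f, moved) == (3, -2)

    def test_shift_recovery_is_exact_under_noise(self, small_volume):
        # SNR >= 10 additive noise, 20 seeded trials
        f = small_volume.frame(0)
        sigma = f.pixels.std() / 10
        rng = np.random.default_rng(0)
        for _ in range(20):
            dz, dx = int(rng.integers(-3, 4)), int(rng.integers(-3, 4))
            noisy = np.roll(f.pixels, (dz, dx), axis=(0, 1)) + \
                sigma * rng.standard_normal(f.pixels.shape)
            moved = f.with_pixels(np.clip(noisy, 0, None))
            assert register_translation(f, moved) == (dz, dx)

    def test_shape_mismatch_rejected(self, small_volume):
        f = small_volume.frame(0)
        g = BScanFrame(f.pixels[:10, :10], 1.0, 1.0)
        from octbrain.core import GeometryError
        with pytest.raises(GeometryError):
            register_translation(f, g)


class TestDespeckle:
    def test_output_count_follows_sliding_window(self):
        frames = np.random.default_rng(0).random((40, 8, 8))
        vol = OCTVolume(frames, VolumeMetadata(pixel_pitch_axial=0.01,
                                               pixel_pitch_lateral=0.01))
        assert len(despeckle_stack(vol, window=10, stride=1)) == 31
        assert len(despeckle_stack(vol, window=10, stride=3)) == 11

    def test_identical_frames_average_to_themselves(self):
        frame = np.random.default_rng(1).random((16, 16))
        vol = OCTVolume(np.stack([frame] * 12),
                        VolumeMetadata(pixel_pitch_axial=0.01, pixel_pitch_lateral=0.01))
        for out in despeckle_stack(vol, window=10):
            assert np.allclose(out.pixels, frame)

    def test_averaging_reduces_speckle_variance_tenfold(self):
        # i.i.d. unit-mean gamma speckle (shape 1), jitter disabled
        rng = np.random.default_rng(2)
        frames = rng.gamma(1.0, 1.0, size=(100, 64, 64))
        vol = OCTVolume(frames, VolumeMetadata(pixel_pitch_axial=0.01,
                                               pixel_pitch_lateral=0.01))
        outs = despeckle_stack(vol, window=10, stride=10, register=False)
        var_out = np.var(np.stack([o.pixels for o in outs]))
        assert var_out == pytest.approx(np.var(frames) / 10, rel=0.10)

    def test_too_few_frames_rejected(self):
        vol = OCTVolume(np.ones((5, 8, 8)),
                        VolumeMetadata(pixel_pitch_axial=0.01, pixel_pitch_lateral=0.01))
        with pytest.raises(InsufficientFramesError):
            despeckle_stack(vol, window=10)

    def test_registration_cancels_known_jitter(self, gbm_phantom, tiny_acq):
        vol = render_volume(gbm_phantom, tiny_acq, n_frames=12, seed=3)
        registered = despeckle_stack(vol, window=10, register=True)
        unregistered = despeckle_stack(vol, window=10, register=False)
        # registered averages must be sharper (higher contrast) than unregistered
        assert registered[0].pixels.std() >= unregistered[0].pixels.std() * 0.99


class TestSaturationFiltering:
    def test_clean_frames_score_below_default_threshold(self, small_volume):
        for k in range(small_volume.n_frames):
            assert saturation_score(small_volume.frame(k)) < 0.02

    def test_five_percent_injection_is_excluded(self, small_volume):
        frame = small_volume.frame(0)
        w = frame.pixels.shape[1]
        bad = inject_saturation(frame, list(range(0, w, 20)))  # 5% of columns
        assert saturation_score(bad) >= 0.05
        assert filter_frames([frame, bad], threshold=0.02) == [frame]

    def test_threshold_one_keeps_everything(self, small_volume):
        frames = [small_volume.frame(k) for k in range(4)]
        frames[0] = inject_saturation(frames[0], list(range(0, 128, 10)))
        assert len(filter_frames(frames, threshold=1.01)) == 4

    @given(t1=st.floats(0.001, 1.0), t2=st.floats(0.001, 1.0))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_raising_threshold_never_drops_frames(self, small_volume, t1, t2):
        lo, hi = sorted([t1, t2])
        frames = [small_volume.frame(k) for k in range(3)]
        frames.append(inject_saturation(frames[0], list(range(0, 128, 8))))
        assert len(filter_frames(frames, hi)) >= len(filter_frames(frames, lo))


class TestStandardize:
    def test_output_contract(self, small_volume):
        out = standardize(small_volume.frame(0))
        assert out.pixels.shape == (128, 256)
        assert out.pixels.min() == 0.0
        assert out.pixels.max() == 1.0

    def test_constant_frame_becomes_zeros_with_warning(self, caplog):
        frame = BScanFrame(np.full((64, 64), 3.0), 2.5, 5.0)
        with caplog.at_level("WARNING", logger="octbrain"):
            out = standardize(frame)
        assert not out.pixels.any()
        assert any("degenerate" in r.message for r in caplog.records)

    def test_idempotence_up_to_resampling_roundoff(self, small_volume):
        once = standardize(small_volume.frame(0))
        twice = standardize(once)
        assert np.max(np.abs(twice.pixels - once.pixels)) < 1e-6

    def test_depth_extent_cropped_to_standard_range(self):
        # 5 mm-deep frame: bottom half is cropped before resampling
        rng = np.random.default_rng(3)
        px = rng.random((200, 64)) + 0.1
        px[100:] = 100.0  # sentinel values beyond 2.5 mm must not survive
        frame = BScanFrame(px, 5.0, 5.0)
        out = standardize(frame)
        assert out.pixels.shape == (128, 256)
        assert out.pixels.max() == 1.0
        assert (out.pixels > 0.99).mean() < 0.05  # sentinel region did not dominate


class TestAugment:
    def test_zero_magnitudes_are_identity(self, small_volume):
        frame = standardize(small_volume.frame(0))
        params = AugmentParams(rotation_deg=0, translation_frac=0, shear=0, zoom=0)
        out = augment(frame, seed=1, params=params)
        assert np.array_equal(out.pixels, frame.pixels)

    def test_same_seed_reproduces_output(self, small_volume):
        frame = standardize(small_volume.frame(0))
        a = augment(frame, seed=42)
        b = augment(frame, seed=42)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.pixels.shape == frame.pixels.shape

    @pytest.mark.parametrize("kwargs", [{"shear": 0.2}, {"zoom": 0.11}])
    def test_shear_and_zoom_hard_cap(self, kwargs):
        with pytest.raises(InvalidParameterError):
            AugmentParams(**kwargs)


class TestRegistrationMarginCrop:
    def test_crop_removes_wrap_seam_borders(self):
        from octbrain.frames import crop_registration_margin

        frame = BScanFrame(np.random.default_rng(0).random((64, 128)), 2.5, 5.0)
        out = crop_registration_margin(frame, margin=3)
        assert out.pixels.shape == (58, 122)
        assert np.array_equal(out.pixels, frame.pixels[3:-3, 3:-3])
        assert out.depth_extent == pytest.approx(2.5 * 58 / 64)

    def test_frame_too_small_for_margin_rejected(self):
        from octbrain.frames import crop_registration_margin

        frame = BScanFrame(np.ones((5, 5)), 1.0, 1.0)
        with pytest.raises(InvalidParameterError):
            crop_registration_margin(frame, margin=3)


class TestPreprocessVolume:
    def test_records_retain_provenance(self, small_dataset):
        out, manifest, _ = small_dataset
        vol = read_volume(manifest.iloc[0]["path"])
        records = preprocess_volume(vol)
        assert len(records) == vol.n_frames - 10 + 1
        for r in records:
            assert r.volume_id == manifest.iloc[0]["volume_id"]
            assert r.frame.pixels.shape == (128, 256)
            assert 0.0 <= r.frame.pixels.min() and r.frame.pixels.max() <= 1.0
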