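"""Feature bank: channel registry, per-block behaviour, training vectors."""

import numpy as np
import pytest
from scipy.ndimage import convolve

import gazevam as gv
from gazevam import pyramids
from gazevam.features import (CHANNEL_NAMES, N_CHANNELS, FeatureStack, FrameContext,
                              build_training_vectors, color_channels,
                              conspicuity_channels, extract_feature_stack,
                              frameset_features, geometry_channels, motion_channel,
                              semantic_channels, steerable_channels)
from gazevam.fixation import CoordinateSample


SHAPE = (60, 100)


def rgb(shape=SHAPE, value=0.5):
    return np.full(shape + (3,), value)


class TestRegistry:
    def test_28_channels_in_canonical_order(self):
        assert N_CHANNELS == 28
        assert len(CHANNEL_NAMES) == 28
        assert sum(n.startswith("steer_") for n in CHANNEL_NAMES) == 13
        assert CHANNEL_NAMES[-1] == "motion"

    def test_stack_rejects_wrong_channel_count(self):
        with pytest.raises(ValueError):
            FeatureStack(np.zeros((27, 10, 10)))

    def test_stack_rejects_nonfinite(self):
        bad = np.zeros((28, 4, 4))
        bad[3, 1, 1] = np.nan
        with pytest.raises(ValueError, match="finite"):
            FeatureStack(bad)


class TestSteerable:
    def test_thirteen_channels(self):
        ch = steerable_channels(np.random.default_rng(0).random(SHAPE))
        assert ch.shape == (13,) + SHAPE
        assert ch.min() >= 0 and ch.max() <= 1

    def test_constant_image_gives_zero_bandpass(self):
        subbands, _ = pyramids.steerable_subbands(np.full(SHAPE, 0.4))
        for b in subbands:
            np.testing.assert_allclose(b, 0.0, atol=1e-10)

    def test_vertical_edge_excites_vertical_tuned_orientations(self):
        img = np.zeros(SHAPE)
        img[:, 50:] = 1.0
        subbands, _ = pyramids.steerable_subbands(img)
        # orientations are (0, 60, 120) deg of edge tuning; a vertical edge
        # (90 deg) is closer to both oblique channels than to horizontal
        for s in range(pyramids.N_SCALES):
            e0, e60, e120 = (subbands[3 * s + i].sum() for i in range(3))
            assert e60 > e0 and e120 > e0

    def test_level0_subband_matches_direct_filtering(self):
        img = np.random.default_rng(3).random(SHAPE)
        subbands, _ = pyramids.steerable_subbands(img)
        k = pyramids.steerable_kernel(pyramids.ORIENTATIONS[0])
        direct = np.abs(convolve(img, k, mode="nearest"))
        np.testing.assert_allclose(subbands[0], direct, atol=1e-12)


class TestConspicuity:
    def test_uniform_gray_color_and_orientation_zero(self):
        ch = conspicuity_channels(rgb(value=0.5))
        color, inten, orient, skin = ch
        np.testing.assert_allclose(color, 0.0, atol=1e-10)
        np.testing.assert_allclose(orient, 0.0, atol=1e-10)

    def test_bright_blob_peaks_intensity_conspicuity(self):
        f = rgb(value=0.0)
        f[28:32, 48:52] = 1.0
        ch = conspicuity_channels(f)
        peak = np.unravel_index(np.argmax(ch[1]), SHAPE)
        assert abs(peak[0] - 30) <= 4 and abs(peak[1] - 50) <= 4

    def test_pure_green_has_no_skin(self):
        f = np.zeros(SHAPE + (3,))
        f[..., 1] = 1.0
        ch = conspicuity_channels(f)
        assert ch[3].max() < 1e-6


class TestColorAndSemantic:
    def test_rgb_round_trip(self):
        f = np.random.default_rng(0).random(SHAPE + (3,))
        ch = color_channels(f)
        np.testing.assert_array_equal(ch[0], f[..., 0])
        np.testing.assert_array_equal(ch[2], f[..., 2])

    def test_oracle_masks_copied_exactly(self, rng):
        face = rng.random(SHAPE) > 0.8
        ch = semantic_channels(rgb(), masks={"face": face, "person": face})
        np.testing.assert_array_equal(ch[1], face.astype(float))
        np.testing.assert_array_equal(ch[0], 0.0)  # no horizon oracle -> zero

    def test_missing_detectors_error(self):
        with pytest.raises(ValueError, match="horizon"):
            semantic_channels(rgb(), masks=None, detectors={})

    def test_detector_stub_band(self):
        band = np.zeros(SHAPE)
        band[10:20] = 1.0
        dets = {k: (lambda f, b=band: b) for k in ("horizon", "face", "people")}
        ch = semantic_channels(rgb(), detectors=dets)
        assert ch[0, 5, 5] == 0 and ch[0, 15, 5] == 1


class TestGeometry:
    def test_center_pixel_distance_zero(self):
        ch = geometry_channels((201, 351), "left")
        assert ch[0][100, 175] == pytest.approx(0.0)

    def test_corner_distance_is_one(self):
        ch = geometry_channels((200, 350), "left")
        assert ch[0][0, 0] == pytest.approx(1.0)

    def test_flags_complementary_and_follow_side(self):
        left = geometry_channels((200, 350), "left")
        bio, geo = left[2], left[3]
        np.testing.assert_array_equal(bio + geo, 1.0)
        assert bio[0, 0] == 1 and bio[0, 349] == 0
        right = geometry_channels((200, 350), "right")
        np.testing.assert_array_equal(right[2], geo)

    def test_scene_distance_symmetric_under_flip(self):
        ch = geometry_channels((200, 350), "left")
        np.testing.assert_allclose(ch[1], ch[1][:, ::-1], atol=1e-12)


class TestMotion:
    def test_identical_frames_zero(self):
        f = rgb()
        np.testing.assert_array_equal(motion_channel(f, f), 0.0)

    def test_first_frame_zero_by_convention(self):
        assert motion_channel(None, rgb()).sum() == 0.0

    def test_moved_block_localized(self):
        a = np.zeros(SHAPE + (3,))
        a[10:20, 10:20] = 1.0
        b = np.zeros(SHAPE + (3,))
        b[10:20, 14:24] = 1.0
        m = motion_channel(a, b)
        oracle = np.abs(b.mean(-1) - a.mean(-1))
        np.testing.assert_allclose(m, oracle, atol=1e-12)
        assert m[:, 30:].sum() == 0.0


class TestStackAssembly:
    def ctx(self, **kw):
        defaults = dict(bio_side="left", masks={"face": np.zeros(SHAPE, bool)})
        defaults.update(kw)
        return FrameContext(**defaults)

    def test_stack_has_28_named_channels(self):
        st = extract_feature_stack(rgb(), self.ctx())
        assert st.channels.shape == (28,) + SHAPE
        assert st.channel_names == CHANNEL_NAMES

    def test_all_black_frame_still_finite(self):
        st = extract_feature_stack(np.zeros(SHAPE + (3,)), self.ctx())
        assert np.isfinite(st.channels).all()
        assert st["flag_biological"][0, 0] == 1.0

    def test_failure_names_the_block(self):
        with pytest.raises(RuntimeError, match="semantic"):
            extract_feature_stack(rgb(), FrameContext(bio_side="left"))

    def test_frameset_mean_equals_elementwise_oracle(self, rng):
        stacks = [FeatureStack(rng.random((28, 5, 6)).astype(np.float32))
                  for _ in range(3)]
        mean = frameset_features(stacks)
        oracle = np.zeros((28, 5, 6))
        for s in stacks:
            oracle += s.channels
        np.testing.assert_allclose(mean.channels, oracle / 3, atol=1e-6)


class TestTrainingVectors:
    def make_sample(self, coords):
        return CoordinateSample(np.asarray(coords), 0, "case")

    def test_vectors_match_stack_columns(self, rng):
        st = FeatureStack(rng.random((28, 10, 12)).astype(np.float32))
        sample = self.make_sample([[2, 3, 1], [7, 11, 0]])
        X, y = build_training_vectors(st, sample)
        assert X.shape == (2, 28)
        np.testing.assert_allclose(X[0], st.channels[:, 2, 3])
        np.testing.assert_array_equal(y, [1, 0])

    def test_700_coordinates_give_700_vectors(self, rng):
        st = FeatureStack(rng.random((28, 200, 350)).astype(np.float32))
        coords = np.column_stack([rng.integers(0, 200, 700),
                                  rng.integers(0, 350, 700),
                                  np.repeat([1, 0], 350)])
        X, y = build_training_vectors(st, self.make_sample(coords))
        assert len(X) == 700 and y.sum() == 350

    def test_out_of_bounds_errors(self, rng):
        st = FeatureStack(rng.random((28, 10, 12)).astype(np.float32))
        with pytest.raises(ValueError, match="outside"):
            build_training_vectors(st, self.make_sample([[10, 3, 1]]))


class TestStackPersistence:
    def test_archive_round_trip(self, tmp_path, rng):
        st = FeatureStack(rng.random((28, 6, 7)).astype(np.float32))
        p = tmp_path / "stack.npz"
        st.save(p)
        back = FeatureStack.load(p)
        np.testing.assert_array_equal(back.channels, st.channels)
        assert back.channel_names == CHANNEL_NAMES
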