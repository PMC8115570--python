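"""Preprocessing contracts: border crop, area resize, transition removal,
and the gaze-to-pixel affine mapping."""

import numpy as np
import pandas as pd
import pytest

import gazevam as gv
from gazevam.preprocess import TARGET_SHAPE, crop_border, map_gaze, remove_transitions, resize_frame, transition_keep_mask
from gazevam.synthetic import Segment, SceneManifest


def manifest_of(seg_lengths, sides=None, screen=(54, 96), fps=10.0):
    sides = sides or ["left" if i % 2 == 0 else "right" for i in range(len(seg_lengths))]
    segs, pos = [], 0
    for n, side in zip(seg_lengths, sides):
        segs.append(Segment(pos, pos + n, side))
        pos += n
    return SceneManifest(tuple(segs), screen, fps)


class TestCropBorder:
    def test_removes_black_margin(self):
        frame = np.zeros((300, 500, 3))
        frame[100:200, 100:400] = 0.5
        cropped, box = crop_border(frame)
        assert box == (100, 200, 100, 400)
        assert cropped.shape == (100, 300, 3)

    def test_borderless_frame_unchanged(self):
        frame = np.full((50, 80, 3), 0.3)
        cropped, box = crop_border(frame)
        assert box == (0, 50, 0, 80)
        np.testing.assert_array_equal(cropped, frame)

    def test_all_black_frame_errors(self):
        with pytest.raises(ValueError, match="all-black"):
            crop_border(np.zeros((10, 10, 3)))


class TestResize:
    def test_output_is_200_by_350(self):
        out = resize_frame(np.random.default_rng(0).random((108, 189, 3)))
        assert out.shape == (200, 350, 3)
        assert out[..., 0].size == 70000  # 200 * 350

    def test_constant_frame_stays_constant(self):
        out = resize_frame(np.full((400, 700), 0.25))
        np.testing.assert_allclose(out, 0.25, atol=1e-12)

    def test_checkerboard_mean_preserved(self):
        # area interpolation is block averaging: global mean is conserved
        board = np.indices((400, 700)).sum(axis=0) % 2 * 1.0
        out = resize_frame(board)
        assert abs(out.mean() - board.mean()) < 0.01 * board.mean()

    def test_uint8_rescaled_to_unit_interval(self):
        out = resize_frame(np.full((40, 70, 3), 255, dtype=np.uint8))
        np.testing.assert_allclose(out, 1.0)


class TestRemoveTransitions:
    def test_nine_sixty_frame_segments_leave_380(self):
        man = manifest_of([60] * 9)
        frames = np.zeros((540, 6, 8))
        seq = remove_transitions(frames, man)
        assert seq.count == 380  # 540 - 8 interior boundaries * 20

    def test_single_segment_untouched(self):
        man = manifest_of([40])
        seq = remove_transitions(np.zeros((40, 6, 8)), man)
        assert seq.count == 40

    def test_short_segment_errors(self):
        man = manifest_of([15, 30])
        with pytest.raises(ValueError, match="15 frames"):
            remove_transitions(np.zeros((45, 6, 8)), man)

    def test_keeps_order_and_only_cuts_boundaries(self):
        man = manifest_of([30, 30])
        frames = np.arange(60, dtype=float)[:, None, None] * np.ones((1, 4, 4))
        seq = remove_transitions(frames, man)
        kept = seq.frames[:, 0, 0].astype(int)
        expected = [*range(0, 20), *range(40, 60)]
        assert kept.tolist() == expected
        assert np.all(np.diff(seq.source_indices) > 0)

    def test_manifest_reindexed(self):
        man = manifest_of([30, 30, 30])
        seq = remove_transitions(np.zeros((90, 4, 4)), man)
        segs = seq.manifest.segments
        assert [(s.start, s.end) for s in segs] == [(0, 20), (20, 30), (30, 50)]
        assert segs[1].n_frames == 10  # interior segment loses both ends


def gaze_df(ts, xs, ys, valid=None, sid="S"):
    n = len(ts)
    return pd.DataFrame({
        "subject_id": [sid] * n, "timestamp_ms": ts,
        "gaze_x_px": xs, "gaze_y_px": ys,
        "validity": valid if valid is not None else [1] * n,
    })


class TestMapGaze:
    frame_times = np.arange(10) * 100.0  # 10 fps

    def test_screen_center_maps_to_frame_center(self):
        df = gaze_df([50.0], [960.0], [540.0])
        st = map_gaze(df, (1080, 1920), (0, 1080, 0, 1920), self.frame_times, 10.0)
        assert (st.row[0], st.col[0]) == (100, 175)

    def test_sample_in_border_excluded(self):
        # crop box leaves a 100 px border; a sample inside it maps out of range
        df = gaze_df([50.0, 51.0], [50.0, 960.0], [50.0, 540.0])
        st = map_gaze(df, (1080, 1920), (100, 980, 100, 1820), self.frame_times, 10.0)
        assert len(st) == 1 and st.n_dropped == 1

    def test_sample_before_first_frame_excluded(self):
        df = gaze_df([-5.0, 20.0], [960.0] * 2, [540.0] * 2)
        st = map_gaze(df, (1080, 1920), (0, 1080, 0, 1920), self.frame_times, 10.0)
        assert len(st) == 1 and st.frame_index[0] == 0

    def test_invalid_samples_excluded(self):
        df = gaze_df([10.0, 20.0], [960.0] * 2, [540.0] * 2, valid=[0, 1])
        st = map_gaze(df, (1080, 1920), (0, 1080, 0, 1920), self.frame_times, 10.0)
        assert len(st) == 1

    def test_non_monotone_timestamps_error(self):
        df = gaze_df([10.0, 5.0], [1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="non-monotone"):
            map_gaze(df, (1080, 1920), (0, 1080, 0, 1920), self.frame_times, 10.0)

    def test_mapping_is_affine_image_of_frame_transform(self, rng):
        # oracle: a pixel's own coordinates, pushed through the crop+resize
        # affine map with floor binning, land on the matching resized pixel
        box = (100, 980, 150, 1870)
        sr = TARGET_SHAPE[0] / (box[1] - box[0])
        sc = TARGET_SHAPE[1] / (box[3] - box[2])
        ys = rng.uniform(box[0], box[1] - 1, 50)
        xs = rng.uniform(box[2], box[3] - 1, 50)
        df = gaze_df(np.sort(rng.uniform(0, 900, 50)), xs, ys)
        st = map_gaze(df, (1080, 1920), box, self.frame_times, 10.0)
        exp_r = np.floor((np.asarray(df.gaze_y_px)[:len(st)] - box[0]) * sr)
        # order is preserved, so compare against the retained samples
        kept = np.isin(np.asarray(df.timestamp_ms), st.t)
        exp_r = np.floor((np.asarray(df.gaze_y_px)[kept] - box[0]) * sr).astype(int)
        exp_c = np.floor((np.asarray(df.gaze_x_px)[kept] - box[2]) * sc).astype(int)
        np.testing.assert_array_equal(st.row, exp_r)
        np.testing.assert_array_equal(st.col, exp_c)

    def test_samples_on_removed_frames_rejected(self):
        man = manifest_of([30, 30], screen=(54, 96))
        seq = remove_transitions(np.zeros((60, 4, 4)), man)
        # frame 25 (0-based) was removed; t=2550 ms falls in its interval
        df = gaze_df([1050.0, 2550.0], [48.0, 48.0], [27.0, 27.0])
        st = map_gaze(df, (54, 96), (0, 54, 0, 96), seq.frame_times, 10.0,
                      source_indices=seq.source_indices)
        assert len(st) == 1
        assert seq.source_indices[st.frame_index[0]] == 10


class TestEndToEnd:
    def test_preprocessed_stimulus_shape(self, tiny_bundle):
        seq = tiny_bundle.sequence
        assert seq.frame_shape == (200, 350)
        assert seq.frames.min() >= 0 and seq.frames.max() <= 1
        # 3 segments of 30 at 10 fps, 2 interior boundaries: 90 - 40 = 50
        assert seq.count == 50

    def test_masks_follow_frames(self, tiny_bundle):
        masks = tiny_bundle.masks
        assert masks["biological"].shape == (50, 200, 350)
        np.testing.assert_array_equal(masks["geometric"], ~masks["biological"])
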