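"""Frame and raw-gaze preprocessing.

Raw stimulus frames carry a black border around the content; preprocessing
crops that border, resizes to a fixed 200x350 grid (area interpolation),
drops the transition frames around each segment boundary (last 10 of one
sub-video, first 10 of the next), and maps raw gaze coordinates through the
identical crop+resize transform so gaze and pixels live on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize_local_mean

from .synthetic import SceneManifest, Segment

TARGET_SHAPE = (200, 350)  # (rows, cols) of every preprocessed frame
BLACK_THRESHOLD = 0.02     # intensity below which a pixel counts as border
N_TRANSITION = 10          # frames dropped on each side of a boundary


@dataclass
class FrameSequence:
    """Ordered preprocessed frames with segment metadata.

    ``frames`` is (T, 200, 350, 3) float in [0, 1]; ``frame_times`` the
    display onset of each frame in ms (strictly increasing, possibly with
    gaps where transition frames were dropped); ``source_indices`` the frame
    numbers in the original video.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    manifest: SceneManifest
    source_indices: np.ndarray | None = None

    def __post_init__(self):
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (T, H, W) or (T, H, W, C)")
        if len(self.frame_times) != len(self.frames):
            raise ValueError("frame_times length mismatch")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def count(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]


@dataclass
class GazeStream:
    """One subject's gaze samples mapped into preprocessed-frame coordinates.

    Only valid samples are kept: row/col inside the frame grid and timestamp
    inside some frame's display interval. ``frame_index`` refers to positions
    in the accompanying FrameSequence.
    """

    subject_id: str
    t: np.ndarray
    row: np.ndarray
    col: np.ndarray
    frame_index: np.ndarray
    n_dropped: int = 0

    def __post_init__(self):
        n = len(self.t)
        if not (len(self.row) == len(self.col) == len(self.frame_index) == n):
            raise ValueError("sample arrays must have equal length")

    def __len__(self) -> int:
        return len(self.t)


def crop_border(frame: np.ndarray, threshold: float = BLACK_THRESHOLD):
    """Crop the black border, returning ``(subimage, (r0, r1, c0, c1))``.

    The box is the tight bounding box of pixels whose intensity exceeds
    ``threshold`` in any channel (frames are taken to [0, 1] first). A frame
    with no border comes back unchanged; an all-black frame is an error.
    """
    if frame.size == 0:
        raise ValueError("empty frame")
    f = frame.astype(np.float64)
    if frame.dtype == np.uint8:
        f = f / 255.0
    lit = f.max(axis=-1) if f.ndim == 3 else f
    rows = np.nonzero((lit > threshold).any(axis=1))[0]
    cols = np.nonzero((lit > threshold).any(axis=0))[0]
    if rows.size == 0:
        raise ValueError("all-black frame: no content to crop to")
    box = (int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)
    return frame[box[0]:box[1], box[2]:box[3]], box


def resize_frame(frame: np.ndarray, shape: tuple[int, int] = TARGET_SHAPE) -> np.ndarray:
    """Area-interpolate (block-average) a cropped frame to ``shape``, in [0,1]."""
    f = frame.astype(np.float64)
    if frame.dtype == np.uint8:
        f = f / 255.0
    out = resize_local_mean(f, shape + f.shape[2:] if f.ndim == 3 else shape)
    return np.clip(out, 0.0, 1.0)


def transition_keep_mask(manifest: SceneManifest,
                         n_transition: int = N_TRANSITION) -> np.ndarray:
    """Boolean mask over original frames: False for dropped transition frames.

    At each interior boundary the last ``n_transition`` frames of the earlier
    segment and the first ``n_transition`` of the later one are dropped.
    """
    for seg in manifest.segments:
        if len(manifest.segments) > 1 and seg.n_frames < 2 * n_transition + 1:
            raise ValueError(
                f"segment [{seg.start}, {seg.end}) has {seg.n_frames} frames; "
                f"needs more than {2 * n_transition} to survive transition removal")
    keep = np.ones(manifest.n_frames, dtype=bool)
    for i, seg in enumerate(manifest.segments):
        if i > 0:
            keep[seg.start:seg.start + n_transition] = False
        if i < len(manifest.segments) - 1:
            keep[seg.end - n_transition:seg.end] = False
    return keep


def _remap_manifest(manifest: SceneManifest, keep: np.ndarray,
                    new_screen: tuple[int, int]) -> SceneManifest:
    counts = np.cumsum(keep)
    segs = []
    pos = 0
    for seg in manifest.segments:
        n = int(counts[seg.end - 1] - (counts[seg.start - 1] if seg.start else 0))
        segs.append(Segment(pos, pos + n, seg.biological_side))
        pos += n
    return SceneManifest(tuple(segs), new_screen, manifest.fps)


def remove_transitions(frames: np.ndarray, manifest: SceneManifest,
                       frame_times: np.ndarray | None = None,
                       n_transition: int = N_TRANSITION) -> FrameSequence:
    """Drop boundary transition frames and re-index times and manifest."""
    if len(frames) != manifest.n_frames:
        raise ValueError(f"{len(frames)} frames but manifest covers {manifest.n_frames}")
    if frame_times is None:
        frame_times = np.arange(len(frames)) * 1000.0 / manifest.fps
    keep = transition_keep_mask(manifest, n_transition)
    new_manifest = _remap_manifest(manifest, keep, frames.shape[1:3])
    idx = np.nonzero(keep)[0]
    return FrameSequence(frames[idx], np.asarray(frame_times)[idx], new_manifest,
                         source_indices=idx)


def map_gaze(raw, original_size: tuple[int, int], crop_box: tuple[int, int, int, int],
             frame_times: np.ndarray, fps: float,
             target_shape: tuple[int, int] = TARGET_SHAPE,
             source_indices: np.ndarray | None = None) -> GazeStream:
    """Map raw screen-coordinate gaze samples into the preprocessed grid.

    ``raw`` is a gaze-dialect DataFrame (timestamp_ms, gaze_x_px, gaze_y_px,
    validity). Coordinates go through the same crop and resize as the frames
    (affine scale then floor to a pixel bin). Samples that are invalid, land
    outside the crop box, or fall outside every kept frame's display interval
    are dropped and counted in ``n_dropped``. ``frame_times`` are the kept
    frames' onsets; ``source_indices`` their original frame numbers (used to
    reject samples landing on removed transition frames).
    """
    ts = np.asarray(raw["timestamp_ms"], dtype=float)
    if np.any(np.diff(ts) < 0):
        raise ValueError("gaze timestamps are non-monotone")
    x = np.asarray(raw["gaze_x_px"], dtype=float)
    y = np.asarray(raw["gaze_y_px"], dtype=float)
    valid = np.asarray(raw["validity"], dtype=int) == 1

    r0, r1, c0, c1 = crop_box
    sr = target_shape[0] / (r1 - r0)
    sc = target_shape[1] / (c1 - c0)
    row = np.floor((y - r0) * sr).astype(int)
    col = np.floor((x - c0) * sc).astype(int)
    inside = (row >= 0) & (row < target_shape[0]) & (col >= 0) & (col < target_shape[1])

    dt = 1000.0 / fps
    if source_indices is not None:
        # assign against the original uninterrupted timeline, then keep only
        # samples whose original frame survived transition removal
        orig_idx = np.floor(ts / dt).astype(int)
        n_orig = int(source_indices.max()) + 1 if len(source_indices) else 0
        lookup = np.full(max(n_orig, 1), -1, dtype=int)
        lookup[source_indices] = np.arange(len(source_indices))
        in_time = (orig_idx >= 0) & (orig_idx < n_orig)
        fidx = np.where(in_time, lookup[np.clip(orig_idx, 0, max(n_orig - 1, 0))], -1)
    else:
        fidx = np.searchsorted(frame_times, ts, side="right") - 1
        in_interval = (fidx >= 0) & (ts < (np.append(frame_times[1:], frame_times[-1] + dt)[np.clip(fidx, 0, None)]))
        fidx = np.where(in_interval, fidx, -1)

    ok = valid & inside & (fidx >= 0)
    sid = str(raw["subject_id"].iloc[0]) if "subject_id" in raw and len(raw) else "?"
    return GazeStream(sid, ts[ok], row[ok], col[ok], fidx[ok],
                      n_dropped=int(len(ts) - ok.sum()))


def preprocess_frames(frames: np.ndarray, manifest: SceneManifest,
                      masks: dict[str, np.ndarray] | None = None,
                      n_transition: int = N_TRANSITION):
    """Full frame pipeline: crop -> resize -> drop transitions.

    The crop box is fitted on the first frame (the stimulus border is static)
    and applied to all frames and oracle masks. Returns
    ``(FrameSequence, resized_masks, crop_box)``; masks are re-binarized at
    0.5 and the biological/geometric pair kept exactly complementary.
    """
    _, box = crop_border(frames[0])
    r0, r1, c0, c1 = box
    T = len(frames)
    out = np.empty((T,) + TARGET_SHAPE + ((3,) if frames.ndim == 4 else ()), dtype=np.float32)
    for t in range(T):
        out[t] = resize_frame(frames[t, r0:r1, c0:c1])
    seq = remove_transitions(out, manifest, n_transition=n_transition)

    small_masks = None
    if masks is not None:
        keep_idx = seq.source_indices
        small_masks = {}
        for key, stack in masks.items():
            sm = np.empty((len(keep_idx),) + TARGET_SHAPE, dtype=bool)
            for j, t in enumerate(keep_idx):
                sm[j] = resize_local_mean(stack[t, r0:r1, c0:c1].astype(float), TARGET_SHAPE) >= 0.5
            small_masks[key] = sm
        if "biological" in small_masks:
            small_masks["geometric"] = ~small_masks["biological"]
    return seq, small_masks, box
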