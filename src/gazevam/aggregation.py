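"""Motion-gated aggregation of consecutive frames and their gaze.

Single video frames carry too few gaze samples to learn from, so consecutive
near-static frames are pooled: a running aggregate (the pixelwise mean of its
members) absorbs the next frame while the mean motion between aggregate and
next frame stays below a threshold (default 0.33, stimulus-specific), and the
gaze samples of member frames are pooled with each set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import FrameSequence, GazeStream


@dataclass(frozen=True)
class AggregationConfig:
    """Motion threshold in (0, 1]; the default was tuned for the stimulus video
    and should be reviewed for any other video."""

    motion_threshold: float = 0.33

    def __post_init__(self):
        if not 0.0 < self.motion_threshold <= 1.0:
            raise ValueError("motion_threshold must be in (0, 1]")


@dataclass
class FrameSet:
    """A contiguous run of aggregated frames.

    ``member_frame_indices`` index into the source FrameSequence;
    ``mean_frame`` is the pixelwise mean of the members; ``motion_to_next``
    the mean motion between this aggregate and the frame that closed it
    (NaN for the final set).
    """

    member_frame_indices: list[int]
    mean_frame: np.ndarray
    motion_to_next: float = float("nan")

    def __len__(self) -> int:
        return len(self.member_frame_indices)


def _to_intensity(frame: np.ndarray) -> np.ndarray:
    return frame.mean(axis=-1) if frame.ndim == 3 else frame


def mean_motion(frame_a: np.ndarray, frame_b: np.ndarray,
                estimator: str = "difference", max_flow_px: float = 10.0) -> float:
    """Mean per-pixel motion between two frames, normalized to [0, 1].

    The default estimator is the absolute temporal intensity difference
    (frames in [0, 1], so each pixel's value is already in [0, 1]); the sum
    over pixels is divided by the pixel count. ``estimator="flow"`` instead
    uses dense optical-flow magnitude (iterative Lucas-Kanade), clipped and
    normalized by ``max_flow_px``.
    """
    if frame_a.shape != frame_b.shape:
        raise ValueError(f"shape mismatch: {frame_a.shape} vs {frame_b.shape}")
    a, b = _to_intensity(np.asarray(frame_a, dtype=np.float64)), _to_intensity(np.asarray(frame_b, dtype=np.float64))
    if estimator == "difference":
        per_pixel = np.abs(a - b)
    elif estimator == "flow":
        from skimage.registration import optical_flow_ilk
        v, u = optical_flow_ilk(a, b)
        per_pixel = np.clip(np.hypot(v, u) / max_flow_px, 0.0, 1.0)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return float(per_pixel.sum() / per_pixel.size)


def aggregate_frames(sequence: FrameSequence | np.ndarray,
                     cfg: AggregationConfig = AggregationConfig(),
                     estimator: str = "difference",
                     boundaries: np.ndarray | None = None) -> list[FrameSet]:
    """Greedy left-to-right aggregation under the motion threshold.

    Maintains a running aggregate; if the mean motion between the aggregate's
    mean frame and the next frame is below the threshold the frame is
    absorbed (and the mean updated), otherwise the set closes and a new one
    starts. The returned sets partition the sequence in order.

    ``boundaries`` (optional, sorted frame positions) force a set to close
    before those positions — used where the frame sequence is not temporally
    contiguous (segment changes, held-out diagnosis frames).
    """
    frames = sequence.frames if isinstance(sequence, FrameSequence) else np.asarray(sequence)
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    forced = set(int(b) for b in boundaries) if boundaries is not None else set()

    sets: list[FrameSet] = []
    members = [0]
    mean = frames[0].astype(np.float64).copy()
    for i in range(1, len(frames)):
        if i in forced:
            m = float("nan")
        else:
            m = mean_motion(mean, frames[i], estimator=estimator)
        if i not in forced and m < cfg.motion_threshold:
            members.append(i)
            n = len(members)
            mean += (frames[i] - mean) / n
        else:
            sets.append(FrameSet(members, mean, motion_to_next=m))
            members = [i]
            mean = frames[i].astype(np.float64).copy()
    sets.append(FrameSet(members, mean))
    return sets


def aggregate_gaze(streams: list[GazeStream], framesets: list[FrameSet]) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Pool gaze per FrameSet: for each set, the (row, col) arrays of every
    stream's samples landing on member frames. Sample counts are conserved:
    each sample belongs to exactly one set."""
    set_of_frame = {}
    for k, fs in enumerate(framesets):
        for f in fs.member_frame_indices:
            set_of_frame[f] = k
    out: list[list[tuple[np.ndarray, np.ndarray]]] = [[] for _ in framesets]
    for stream in streams:
        if len(stream) == 0:
            continue
        owner = np.array([set_of_frame.get(int(f), -1) for f in stream.frame_index])
        for k in range(len(framesets)):
            sel = owner == k
            if sel.any():
                out[k].append((stream.row[sel], stream.col[sel]))
    return out
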