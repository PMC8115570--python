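"""The 28-channel per-pixel feature bank.

Every preprocessed frame is described by 28 aligned 200x350 channels, in a
frozen canonical order:

* 13 steerable-pyramid maps — 4 scales x 3 orientations of band-pass
  magnitude plus the low-pass residual;
* 4 conspicuity maps (color opponency, intensity, orientation energy, skin);
* 3 RGB channels;
* 3 semantic score maps (horizon, face, people) from oracle masks or
  pluggable detectors;
* 4 geometry channels — normalized distance to the frame center and to the
  center of the pixel's half-screen scene, plus the binary
  biological/geometric scene flags;
* 1 motion magnitude channel against the previous frame.

Structure channels are min-max scaled per frame to [0, 1]; flags, distances
and RGB have fixed analytic ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import pyramids
from .detectors import DetectorFn, skin_probability

_STEER = [f"steer_s{s}_o{int(o)}" for s in range(pyramids.N_SCALES)
          for o in pyramids.ORIENTATIONS] + ["steer_lowpass"]
CHANNEL_NAMES: tuple[str, ...] = tuple(
    _STEER
    + ["consp_color", "consp_intensity", "consp_orientation", "consp_skin"]
    + ["rgb_r", "rgb_g", "rgb_b"]
    + ["sem_horizon", "sem_face", "sem_people"]
    + ["geom_dist_frame_center", "geom_dist_scene_center",
       "flag_biological", "flag_geometric"]
    + ["motion"]
)
N_CHANNELS = len(CHANNEL_NAMES)
assert N_CHANNELS == 28

FLAG_CHANNELS = ("flag_biological", "flag_geometric")


@dataclass
class FeatureStack:
    """(28, H, W) channel tensor with its canonical channel names."""

    channels: np.ndarray
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    frame_id: int | None = None

    def __post_init__(self):
        if self.channels.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.channels.shape[0]} channels but {len(self.channel_names)} names")
        if self.channel_names != CHANNEL_NAMES:
            raise ValueError("channel names do not match the canonical registry")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("non-finite values in feature stack")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[CHANNEL_NAMES.index(name)]

    def save(self, path) -> None:
        """Persist as a compressed array archive with a channel-name sidecar."""
        np.savez_compressed(path, channels=self.channels,
                            channel_names=np.array(self.channel_names))

    @classmethod
    def load(cls, path) -> "FeatureStack":
        with np.load(path, allow_pickle=False) as z:
            names = tuple(str(n) for n in z["channel_names"])
            return cls(z["channels"], names)


@dataclass
class FrameContext:
    """Everything a frame needs besides its own pixels.

    ``masks`` maps oracle-mask names ('face', 'person', 'biological', ...) to
    boolean maps; when given, semantic channels copy them exactly (missing
    keys mean the scene lacks that object: zero map). Without masks,
    ``detectors`` must provide a callable per semantic channel.
    """

    bio_side: str                       # 'left' or 'right' for this frame
    prev_frame: np.ndarray | None = None
    masks: dict[str, np.ndarray] | None = None
    detectors: dict[str, DetectorFn] | None = None
    frame_id: int | None = None


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < 1e-12:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def steerable_channels(gray: np.ndarray) -> np.ndarray:
    """12 oriented band-pass magnitude maps + low-pass residual, each in [0,1]."""
    subbands, residual = pyramids.steerable_subbands(gray)
    maps = [_minmax(b) for b in subbands] + [_minmax(residual)]
    return np.stack(maps)


def conspicuity_channels(frame: np.ndarray) -> np.ndarray:
    """Itti-style color/intensity/orientation conspicuity plus skin, in [0,1]."""
    f = np.asarray(frame, dtype=np.float64)
    r, g, b = f[..., 0], f[..., 1], f[..., 2]
    intensity = f.mean(axis=-1)
    rg = r - g
    by = b - (r + g) / 2.0
    color = pyramids.center_surround(rg) + pyramids.center_surround(by)
    inten = pyramids.center_surround(intensity)
    subbands, _ = pyramids.steerable_subbands(intensity)
    orient = np.sum(subbands, axis=0)
    skin = skin_probability(f)  # already an analytic [0,1] likelihood
    return np.stack([_minmax(color), _minmax(inten), _minmax(orient), skin])


def color_channels(frame: np.ndarray) -> np.ndarray:
    f = np.asarray(frame, dtype=np.float64)
    return np.stack([f[..., 0], f[..., 1], f[..., 2]])


def semantic_channels(frame: np.ndarray, masks: dict | None = None,
                      detectors: dict[str, DetectorFn] | None = None) -> np.ndarray:
    """Horizon / face / people score maps in [0, 1].

    Oracle masks win when provided (synthetic stimuli), keyed 'horizon',
    'face', 'person'/'people'; absent keys yield zero maps. Otherwise each
    channel needs a registered detector.
    """
    shape = frame.shape[:2]
    if masks is not None:
        def m(*keys):
            for k in keys:
                if k in masks:
                    return np.asarray(masks[k], dtype=np.float64)
            return np.zeros(shape)
        return np.stack([m("horizon"), m("face"), m("person", "people")])
    if detectors is None:
        raise ValueError("semantic channels need oracle masks or detectors "
                         "for: horizon, face, people")
    out = []
    for key in ("horizon", "face", "people"):
        if key not in detectors:
            raise ValueError(f"no detector registered for semantic channel {key!r}")
        out.append(np.clip(detectors[key](frame), 0.0, 1.0))
    return np.stack(out)


@lru_cache(maxsize=8)
def _geometry_cache(shape: tuple[int, int], bio_side: str) -> tuple[np.ndarray, ...]:
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    d_frame = np.hypot(rows - cy, cols - cx)
    d_frame /= np.hypot(cy, cx)  # farthest corner of the frame

    mid = w // 2
    left = cols < mid
    d_scene = np.empty((h, w))
    for sel, (lo, hi) in ((left, (0, mid)), (~left, (mid, w))):
        sy, sx = (h - 1) / 2.0, (lo + hi - 1) / 2.0
        d = np.hypot(rows - sy, cols - sx)
        dmax = np.hypot(sy, sx - lo)  # farthest corner of the half
        d_scene[sel] = (d / dmax)[sel]
    bio = left if bio_side == "left" else ~left
    return d_frame, np.clip(d_scene, 0, 1), bio.astype(np.float64), (~bio).astype(np.float64)


def geometry_channels(shape: tuple[int, int], bio_side: str) -> np.ndarray:
    """Distance-to-frame-center, distance-to-scene-center (each normalized by
    the farthest reachable corner), and the complementary scene flags."""
    if bio_side not in ("left", "right"):
        raise ValueError(f"bio_side must be 'left' or 'right', got {bio_side!r}")
    return np.stack(_geometry_cache(tuple(shape), bio_side))


def motion_channel(prev_frame: np.ndarray | None, frame: np.ndarray) -> np.ndarray:
    """Per-pixel motion magnitude vs the previous frame; zeros for the first
    frame of a sequence. Same estimator family as frame aggregation."""
    gray = frame.mean(axis=-1) if frame.ndim == 3 else frame
    if prev_frame is None:
        return np.zeros_like(gray)
    pg = prev_frame.mean(axis=-1) if prev_frame.ndim == 3 else prev_frame
    return np.clip(np.abs(gray - pg), 0.0, 1.0)


def extract_feature_stack(frame: np.ndarray, context: FrameContext) -> FeatureStack:
    """Assemble all 28 channels for one preprocessed frame, canonical order."""
    f = np.asarray(frame, dtype=np.float64)
    gray = f.mean(axis=-1)
    blocks = {
        "steerable": lambda: steerable_channels(gray),
        "conspicuity": lambda: conspicuity_channels(f),
        "rgb": lambda: color_channels(f),
        "semantic": lambda: semantic_channels(f, context.masks, context.detectors),
        "geometry": lambda: geometry_channels(f.shape[:2], context.bio_side),
        "motion": lambda: motion_channel(context.prev_frame, f)[None],
    }
    parts = []
    for name, fn in blocks.items():
        try:
            parts.append(fn())
        except Exception as e:
            raise RuntimeError(f"feature block {name!r} failed: {e}") from e
    stack = np.concatenate(parts, axis=0).astype(np.float32)
    return FeatureStack(stack, CHANNEL_NAMES, frame_id=context.frame_id)


def frameset_features(stacks: list[FeatureStack]) -> FeatureStack:
    """Pixelwise mean of member-frame stacks (the aggregated feature stack)."""
    if not stacks:
        raise ValueError("need at least one member stack")
    mean = np.mean([s.channels for s in stacks], axis=0)
    return FeatureStack(mean.astype(np.float32), CHANNEL_NAMES)


def build_training_vectors(stack: FeatureStack, sample) -> tuple[np.ndarray, np.ndarray]:
    """Extract one labeled vector per selected coordinate.

    Returns ``(X, y)`` with X of shape (n_coords, 28) and y in {0, 1}; raises
    on out-of-bounds coordinates.
    """
    coords = sample.coords
    h, w = stack.channels.shape[1:]
    if coords[:, 0].min() < 0 or coords[:, 0].max() >= h \
            or coords[:, 1].min() < 0 or coords[:, 1].max() >= w:
        raise ValueError("coordinate outside the frame grid")
    X = stack.channels[:, coords[:, 0], coords[:, 1]].T.astype(np.float64)
    y = coords[:, 2].astype(np.float64)
    return X, y
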