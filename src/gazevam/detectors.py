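"""Semantic detector interface and default heuristic detectors.

The semantic channels (horizon, face, people) are pluggable: any callable
taking an RGB frame in [0, 1] and returning a same-shaped score map in
[0, 1] satisfies the interface. Synthetic runs pass oracle masks instead and
never touch these. The defaults here are deliberately simple image
heuristics — a skin-chrominance blob scorer for faces, a skin+motion scorer
for people, and a dominant-gradient-band scorer for the horizon — intended
as reasonable zero-dependency baselines for real footage, and replaceable
per channel via the detector registry.
"""

from __future__ import annotations

from typing import Callable, Protocol

import numpy as np
from scipy.ndimage import gaussian_filter

DetectorFn = Callable[[np.ndarray], np.ndarray]


class DetectorInterface(Protocol):
    name: str

    def __call__(self, frame: np.ndarray) -> np.ndarray: ...


def skin_probability(frame: np.ndarray) -> np.ndarray:
    """Chrominance-based skin likelihood in [0, 1] (normalized-rg locus)."""
    f = np.asarray(frame, dtype=np.float64)
    total = f.sum(axis=-1) + 1e-9
    r = f[..., 0] / total
    g = f[..., 1] / total
    d2 = (r - 0.45) ** 2 + (g - 0.31) ** 2
    return np.exp(-d2 / (2 * 0.06 ** 2))


class SkinBlobFaceDetector:
    """Scores compact high-skin-probability blobs; peaks at blob centers."""

    name = "skin_blob_face"

    def __init__(self, threshold: float = 0.5, blur_px: float = 3.0):
        self.threshold = threshold
        self.blur_px = blur_px

    def __call__(self, frame: np.ndarray) -> np.ndarray:
        skin = skin_probability(frame)
        blob = gaussian_filter((skin > self.threshold).astype(float), self.blur_px)
        m = blob.max()
        return blob / m if m > 0 else blob


class SkinMotionPeopleDetector:
    """People score: smoothed skin likelihood, optionally gated by motion."""

    name = "skin_motion_people"

    def __init__(self, blur_px: float = 6.0):
        self.blur_px = blur_px
        self._prev: np.ndarray | None = None

    def __call__(self, frame: np.ndarray) -> np.ndarray:
        score = gaussian_filter(skin_probability(frame), self.blur_px)
        if self._prev is not None and self._prev.shape == frame.shape:
            gray = frame.mean(axis=-1)
            motion = gaussian_filter(np.abs(gray - self._prev.mean(axis=-1)), self.blur_px)
            mm = motion.max()
            if mm > 0:
                score = 0.5 * score + 0.5 * motion / mm
        self._prev = np.asarray(frame, dtype=np.float64)
        m = score.max()
        return score / m if m > 0 else score


class GradientBandHorizonDetector:
    """Scores rows by horizontal-edge strength; emits a band at the peak row."""

    name = "gradient_band_horizon"

    def __init__(self, band_sigma_px: float = 5.0):
        self.band_sigma_px = band_sigma_px

    def __call__(self, frame: np.ndarray) -> np.ndarray:
        gray = frame.mean(axis=-1) if frame.ndim == 3 else frame
        dy = np.abs(np.diff(gray, axis=0)).sum(axis=1)
        if dy.max() <= 0:
            return np.zeros_like(gray)
        peak = int(np.argmax(dy))
        rows = np.arange(gray.shape[0])
        band = np.exp(-((rows - peak) ** 2) / (2 * self.band_sigma_px ** 2))
        return np.tile(band[:, None], (1, gray.shape[1]))


def default_detectors() -> dict[str, DetectorFn]:
    return {
        "face": SkinBlobFaceDetector(),
        "people": SkinMotionPeopleDetector(),
        "horizon": GradientBandHorizonDetector(),
    }
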