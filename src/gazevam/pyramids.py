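"""Multi-scale oriented decomposition and center-surround helpers.

The oriented subbands come from steerable second-derivative-of-Gaussian
filters applied at each level of a Gaussian pyramid: four scales, three
orientations, plus a low-pass residual, all upsampled back to frame size.
The same pyramid utilities drive the Itti-style center-surround conspicuity
maps.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve, gaussian_filter
from skimage.transform import resize

N_SCALES = 4
# tuned edge orientations in degrees; the filter differentiates perpendicular
# to the tuned orientation, so a vertical edge excites the 60/120 channels
# more than the 0 (horizontal) channel
ORIENTATIONS = (0.0, 60.0, 120.0)


def steerable_kernel(theta_deg: float, sigma: float = 1.2, radius: int = 4) -> np.ndarray:
    """Second directional derivative of a Gaussian, tuned to edges at
    ``theta_deg`` (derivative taken along ``theta_deg + 90``). Zero-mean."""
    d = np.deg2rad(theta_deg + 90.0)
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    u = xx * np.cos(d) + yy * np.sin(d)
    g = np.exp(-(xx ** 2 + yy ** 2) / (2 * sigma ** 2))
    k = (u ** 2 / sigma ** 4 - 1.0 / sigma ** 2) * g
    k -= k.mean()
    norm = np.abs(k).sum()
    return k / norm


def gaussian_pyramid(image: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Level 0 is the input; each next level is blurred and decimated by 2."""
    levels = [np.asarray(image, dtype=np.float64)]
    for _ in range(n_levels - 1):
        prev = levels[-1]
        if min(prev.shape[:2]) < 4:
            break
        levels.append(gaussian_filter(prev, sigma=1.0, mode="nearest")[::2, ::2])
    return levels


def steerable_subbands(gray: np.ndarray, n_scales: int = N_SCALES,
                       orientations=ORIENTATIONS):
    """Oriented band-pass magnitude maps plus the low-pass residual.

    Returns ``(subbands, residual)`` where ``subbands`` is a list of
    ``n_scales * len(orientations)`` maps (scale-major order), each the
    absolute filter response upsampled to the input size, and ``residual``
    the blurred coarsest level upsampled likewise.
    """
    shape = gray.shape
    pyr = gaussian_pyramid(gray, n_scales)
    kernels = [steerable_kernel(th) for th in orientations]
    out = []
    for s in range(n_scales):
        level = pyr[min(s, len(pyr) - 1)]
        for k in kernels:
            resp = np.abs(convolve(level, k, mode="nearest"))
            out.append(resize(resp, shape, order=1, anti_aliasing=False))
    residual = gaussian_filter(pyr[-1], sigma=1.0, mode="nearest")
    return out, resize(residual, shape, order=1, anti_aliasing=False)


def center_surround(image: np.ndarray, centers=(1, 2), deltas=(2, 3)) -> np.ndarray:
    """Sum of |center - surround| maps across pyramid level pairs.

    Center levels ``c`` are compared against surround levels ``c + delta``
    (surround upsampled to the center's grid); all maps are upsampled to the
    input size and summed — the across-scale combination of the classic
    saliency architecture.
    """
    shape = image.shape
    max_level = max(c + d for c in centers for d in deltas) + 1
    pyr = gaussian_pyramid(image, max_level)
    acc = np.zeros(shape, dtype=np.float64)
    for c in centers:
        if c >= len(pyr):
            continue
        for d in deltas:
            s = min(c + d, len(pyr) - 1)
            if s <= c:
                continue
            surround = resize(pyr[s], pyr[c].shape, order=1, anti_aliasing=False)
            cs = np.abs(pyr[c] - surround)
            acc += resize(cs, shape, order=1, anti_aliasing=False)
    return acc
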