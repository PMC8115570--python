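"""Fixation maps and balanced training-coordinate selection.

A group fixation map accumulates every group subject's gaze landings on a
frame set into per-pixel counts and smooths them with a normalized 5x5
Gaussian. From each map, the top-350 cells become class-1 (fixated) training
coordinates and 350 uniformly sampled exactly-zero cells become class-0,
giving 700 balanced coordinates per map. An individual fixation map is the
plain binary hit mask of one subject's samples on one frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve

from .preprocess import TARGET_SHAPE, GazeStream


@dataclass
class GroupFixationMap:
    counts: np.ndarray            # smoothed, >= 0
    frameset_id: int
    group: str
    raw_counts: np.ndarray | None = None


@dataclass
class IndividualFixationMap:
    bits: np.ndarray              # {0,1} uint8
    subject_id: str
    frame_id: int


@dataclass
class CoordinateSample:
    """Balanced labeled coordinates: rows of (row, col, class)."""

    coords: np.ndarray            # (n, 3) int
    frameset_id: int
    group: str

    @property
    def n_pos(self) -> int:
        return int((self.coords[:, 2] == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.coords[:, 2] == 0).sum())


def gaussian_kernel(size: int = 5, sigma: float = 1.0) -> np.ndarray:
    """Odd-sized 2-D Gaussian kernel normalized to unit sum."""
    if size % 2 != 1 or size < 1:
        raise ValueError("kernel size must be odd and positive")
    ax = np.arange(size) - size // 2
    g = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def accumulate_counts(gaze_chunks, shape: tuple[int, int] = TARGET_SHAPE) -> np.ndarray:
    """Sum gaze landings into a count matrix.

    ``gaze_chunks`` is an iterable of (rows, cols) index arrays — one chunk
    per subject, as produced by :func:`gazevam.aggregation.aggregate_gaze`.
    """
    counts = np.zeros(shape, dtype=np.float64)
    for rows, cols in gaze_chunks:
        np.add.at(counts, (np.asarray(rows, dtype=int), np.asarray(cols, dtype=int)), 1.0)
    return counts


def group_fixation_map(gaze_chunks, frameset_id: int, group: str,
                       kernel: np.ndarray | None = None,
                       shape: tuple[int, int] = TARGET_SHAPE) -> GroupFixationMap:
    """Accumulate all group subjects' samples on one frame set and smooth.

    Smoothing uses a unit-sum 5x5 Gaussian (sigma 1 px) with zero padding,
    so total mass is conserved except at the frame boundary.
    """
    raw = accumulate_counts(gaze_chunks, shape)
    k = gaussian_kernel() if kernel is None else kernel
    smoothed = convolve(raw, k, mode="constant", cval=0.0)
    return GroupFixationMap(smoothed, frameset_id, group, raw_counts=raw)


def individual_fixation_map(stream: GazeStream, frame_id: int,
                            shape: tuple[int, int] = TARGET_SHAPE,
                            dilation_radius: int = 0) -> IndividualFixationMap:
    """Binary hit mask of one subject's valid samples on one frame.

    A pixel is 1 iff at least one sample landed there (repeat hits do not
    stack). ``dilation_radius`` optionally thickens hits with a disk; the
    default 0 matches the plain binarized-raw-hits definition.
    """
    bits = np.zeros(shape, dtype=np.uint8)
    sel = stream.frame_index == frame_id
    bits[stream.row[sel], stream.col[sel]] = 1
    if dilation_radius > 0:
        from scipy.ndimage import binary_dilation
        r = dilation_radius
        ax = np.arange(-r, r + 1)
        disk = ax[:, None] ** 2 + ax[None, :] ** 2 <= r ** 2
        bits = binary_dilation(bits.astype(bool), structure=disk).astype(np.uint8)
    return IndividualFixationMap(bits, stream.subject_id, frame_id)


def export_map(fmap: GroupFixationMap, basepath) -> tuple:
    """Write a fixation map for inspection: 16-bit PNG plus tab-delimited text.

    The PNG scales the map to the full 16-bit range (max value -> 65535);
    the TSV holds the raw smoothed values. Returns the two paths.
    """
    import imageio.v3 as iio
    from pathlib import Path

    base = Path(basepath)
    png = base.with_suffix(".png")
    tsv = base.with_suffix(".tsv")
    v = fmap.counts
    scale = 65535.0 / v.max() if v.max() > 0 else 0.0
    iio.imwrite(png, (v * scale).astype(np.uint16))
    np.savetxt(tsv, v, delimiter="\t", fmt="%.6g")
    return png, tsv


def select_coordinates(fmap: GroupFixationMap, n_pos: int = 350, n_neg: int = 350,
                       seed: int = 0) -> CoordinateSample:
    """Pick the top ``n_pos`` cells (class 1) and ``n_neg`` random zero cells.

    Class 1 takes the cells with the highest smoothed values, ties broken by
    (value desc, row asc, col asc) so the choice is deterministic. Class 0 is
    drawn uniformly without replacement from cells whose value is exactly
    zero. Raises with the deficit if the map lacks enough nonzero or zero
    cells.
    """
    values = fmap.counts
    flat = values.ravel()
    n_nonzero = int((flat > 0).sum())
    n_zero = int((flat == 0).sum())
    if n_nonzero < n_pos:
        raise ValueError(f"map has only {n_nonzero} cells > 0; need {n_pos} for class 1")
    if n_zero < n_neg:
        raise ValueError(f"map has only {n_zero} zero cells; need {n_neg} for class 0")

    h, w = values.shape
    rows, cols = np.divmod(np.arange(flat.size), w)
    # lexsort: last key is primary
    order = np.lexsort((cols, rows, -flat))
    top = order[:n_pos]

    zero_idx = np.nonzero(flat == 0)[0]
    rng = np.random.default_rng(seed)
    neg = rng.choice(zero_idx, size=n_neg, replace=False)

    coords = np.empty((n_pos + n_neg, 3), dtype=int)
    coords[:n_pos, 0], coords[:n_pos, 1], coords[:n_pos, 2] = rows[top], cols[top], 1
    coords[n_pos:, 0], coords[n_pos:, 1], coords[n_pos:, 2] = rows[neg], cols[neg], 0
    return CoordinateSample(coords, fmap.frameset_id, fmap.group)
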