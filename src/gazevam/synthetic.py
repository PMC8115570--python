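"""Synthetic two-panel stimulus videos and group-conditional gaze streams.

The clinical paradigm shows a screen split into two halves: one with
biological motion (people interacting, faces) and one with geometric/fractal
motion, the sides swapping between segments so subjects are not conditioned
to one side. Real footage and patient gaze are not redistributable, so this
module renders a proxy stimulus (textured moving ellipse "people" with an
embedded high-contrast face disc on one half, a rotating polygon field on the
other) together with per-frame oracle masks, and simulates gaze as a mixture
of face-directed, scene-center-directed and uniform-noise samples whose
weights encode a phenotype.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Segment", "SceneManifest", "PhenotypeParams", "default_manifest",
    "generate_stimulus", "generate_gaze", "write_fixtures",
]


@dataclass(frozen=True)
class Segment:
    """One sub-video: frame range [start, end) and which half is biological."""

    start: int
    end: int
    biological_side: str  # "left" or "right"

    def __post_init__(self):
        if self.biological_side not in ("left", "right"):
            raise ValueError(f"biological_side must be 'left' or 'right', got {self.biological_side!r}")
        if self.end <= self.start:
            raise ValueError(f"empty segment [{self.start}, {self.end})")

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SceneManifest:
    """Segment layout of a two-panel stimulus video.

    Segments must be contiguous, non-overlapping and cover frames
    [0, n_frames). ``screen_size`` is (height, width) in pixels.
    """

    segments: tuple[Segment, ...]
    screen_size: tuple[int, int]
    fps: float

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValueError("manifest needs at least one segment")
        if self.segments[0].start != 0:
            raise ValueError("first segment must start at frame 0")
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start != a.end:
                raise ValueError(f"segments not contiguous at frame {a.end} vs {b.start}")
        h, w = self.screen_size
        if h <= 0 or w <= 0 or self.fps <= 0:
            raise ValueError("screen_size and fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.segments[-1].end

    def side_of_frame(self, frame_index: int) -> str:
        """Biological side ('left'/'right') for the segment containing the frame."""
        for seg in self.segments:
            if seg.start <= frame_index < seg.end:
                return seg.biological_side
        raise IndexError(f"frame {frame_index} outside manifest range [0, {self.n_frames})")

    def segment_of_frame(self, frame_index: int) -> int:
        for i, seg in enumerate(self.segments):
            if seg.start <= frame_index < seg.end:
                return i
        raise IndexError(f"frame {frame_index} outside manifest range [0, {self.n_frames})")


@dataclass(frozen=True)
class PhenotypeParams:
    """Gaze-generator mixture weights describing one group's looking behaviour.

    p_geometric
        Probability that a sample lands on the geometric half. The paradigm's
        headline group contrast: cases prefer geometric motion.
    center_bias_sigma
        Std-dev (px) of the Gaussian around the chosen half's center.
    face_attraction
        Given the biological half, probability mass aimed at the face mask
        centroid rather than the scene center.
    dropout_rate
        Fraction of ticks with no emitted sample (tracker data loss).
    uniform_noise
        Within-side uniform scatter weight (calibration error, stray looks).
    """

    p_geometric: float = 0.5
    center_bias_sigma: float = 40.0
    face_attraction: float = 0.5
    dropout_rate: float = 0.05
    uniform_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("p_geometric", "face_attraction", "dropout_rate", "uniform_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.center_bias_sigma <= 0:
            raise ValueError("center_bias_sigma must be > 0")


def default_manifest(n_segments: int = 9, segment_seconds: float = 6.0,
                     fps: float = 10.0, screen_size: tuple[int, int] = (270, 480)) -> SceneManifest:
    """Nine 6-second segments with the biological half alternating sides.

    The stimulus is rendered at 270x480 (same 16:9 aspect as the original
    1920x1080 display); preprocessing resizes to 200x350 regardless, so the
    render scale only bounds memory.
    """
    per = int(round(segment_seconds * fps))
    segs = [Segment(i * per, (i + 1) * per, "left" if i % 2 == 0 else "right")
            for i in range(n_segments)]
    return SceneManifest(tuple(segs), screen_size, fps)


# fraction of each screen dimension taken by the black margin (per side)
_MARGIN = 0.06

MASK_KEYS = ("face", "person", "biological", "geometric")


def _content_box(h: int, w: int) -> tuple[int, int, int, int]:
    mr, mc = int(round(h * _MARGIN)), int(round(w * _MARGIN))
    return mr, h - mr, mc, w - mc


def generate_stimulus(manifest: SceneManifest, seed: int = 0):
    """Render the stimulus video and per-frame oracle masks.

    Returns ``(frames, masks)`` where ``frames`` is a (T, H, W, 3) uint8 array
    and ``masks`` maps each of ``MASK_KEYS`` to a (T, H, W) bool array. The
    biological half carries a cluster of textured moving ellipses ("people")
    with a bright face disc; the geometric half a field of rotating polygons.
    Content (trajectories, textures) is re-drawn per segment.
    """
    if not isinstance(manifest, SceneManifest):
        raise TypeError("manifest must be a SceneManifest")
    h, w = manifest.screen_size
    T = manifest.n_frames
    frames = np.zeros((T, h, w, 3), dtype=np.uint8)
    masks = {k: np.zeros((T, h, w), dtype=bool) for k in MASK_KEYS}

    r0, r1, c0, c1 = _content_box(h, w)
    ch, cw = r1 - r0, c1 - c0
    half = cw // 2
    gw = cw - half  # geometric panel width
    yy, xx = np.mgrid[0:ch, 0:half]
    gyy, gxx = np.mgrid[0:ch, 0:gw]

    rng = np.random.default_rng(seed)
    for si, seg in enumerate(manifest.segments):
        seg_rng = np.random.default_rng(rng.integers(0, 2**31))
        bio_left = seg.biological_side == "left"
        # per-segment randomized content
        n_people = 3
        phases = seg_rng.uniform(0, 2 * np.pi, (n_people, 2))
        speeds = seg_rng.uniform(0.3, 1.2, (n_people, 2))
        radii = seg_rng.uniform(0.10, 0.16, n_people) * ch
        person_base = np.stack([seg_rng.uniform(0.3, 0.7, n_people) * ch,
                                seg_rng.uniform(0.25, 0.75, n_people) * half], axis=1)
        tex = (seg_rng.random((ch, half)) * 0.3 + 0.25)  # static cloth texture
        # the geometric half is textured too: the clinical stimuli are rich
        # video on both halves, so neither half should be mostly background
        tex_geo = (seg_rng.random((ch, cw - half)) * 0.3 + 0.25)
        n_poly = 4
        poly_centers = np.stack([seg_rng.uniform(0.2, 0.8, n_poly) * ch,
                                 seg_rng.uniform(0.2, 0.8, n_poly) * half], axis=1)
        poly_sides = seg_rng.integers(3, 7, n_poly)
        poly_radius = seg_rng.uniform(0.12, 0.22, n_poly) * ch
        poly_spin = seg_rng.uniform(-0.15, 0.15, n_poly)
        poly_color = seg_rng.uniform(0.4, 1.0, (n_poly, 3))

        for t in range(seg.start, seg.end):
            tt = t - seg.start
            bio = np.zeros((ch, half, 3), dtype=np.float64)
            face_m = np.zeros((ch, half), dtype=bool)
            person_m = np.zeros((ch, half), dtype=bool)
            bio[..., 0] = tex * 0.5
            bio[..., 1] = tex * 0.45
            bio[..., 2] = tex * 0.4
            for p in range(n_people):
                cy = person_base[p, 0] + 0.12 * ch * np.sin(speeds[p, 0] * tt * 0.2 + phases[p, 0])
                cx = person_base[p, 1] + 0.12 * half * np.sin(speeds[p, 1] * tt * 0.2 + phases[p, 1])
                body = ((yy - cy) / (1.6 * radii[p])) ** 2 + ((xx - cx) / radii[p]) ** 2 <= 1.0
                person_m |= body
                bio[body] = (0.55, 0.35, 0.25)
                fr = 0.35 * radii[p]
                fy = cy - 1.1 * radii[p]
                face = (yy - fy) ** 2 + (xx - cx) ** 2 <= fr ** 2
                face_m |= face
                bio[face] = (0.95, 0.8, 0.7)

            geo = np.empty((ch, gw, 3), dtype=np.float64)
            geo[..., 0] = tex_geo * 0.45
            geo[..., 1] = tex_geo * 0.5
            geo[..., 2] = tex_geo * 0.55
            for q in range(n_poly):
                ang = np.arctan2(gyy - poly_centers[q, 0], gxx - poly_centers[q, 1])
                rad = np.hypot(gyy - poly_centers[q, 0], gxx - poly_centers[q, 1])
                k = poly_sides[q]
                # regular-polygon boundary radius as a function of angle
                a = np.mod(ang + poly_spin[q] * tt, 2 * np.pi / k) - np.pi / k
                rb = poly_radius[q] * np.cos(np.pi / k) / np.cos(a)
                inside = rad <= rb
                geo[inside] = poly_color[q]

            content = np.empty((ch, cw, 3), dtype=np.float64)
            fmask = np.zeros((ch, cw), dtype=bool)
            pmask = np.zeros((ch, cw), dtype=bool)
            bmask = np.zeros((ch, cw), dtype=bool)
            if bio_left:
                content[:, :half] = bio
                content[:, half:] = geo
                fmask[:, :half] = face_m
                pmask[:, :half] = person_m
                bmask[:, :half] = True
            else:
                content[:, gw:] = bio
                content[:, :gw] = geo
                fmask[:, gw:] = face_m
                pmask[:, gw:] = person_m
                bmask[:, gw:] = True

            frames[t, r0:r1, c0:c1] = np.clip(content * 255, 0, 255).astype(np.uint8)
            masks["face"][t, r0:r1, c0:c1] = fmask
            masks["person"][t, r0:r1, c0:c1] = pmask
            masks["biological"][t, r0:r1, c0:c1] = bmask
            masks["geometric"][t, r0:r1, c0:c1] = ~bmask
        del si
    return frames, masks


def face_centroids(face_masks: np.ndarray) -> np.ndarray:
    """Per-frame (row, col) centroid of the face mask; NaN where empty."""
    T = face_masks.shape[0]
    out = np.full((T, 2), np.nan)
    for t in range(T):
        rows, cols = np.nonzero(face_masks[t])
        if rows.size:
            out[t] = rows.mean(), cols.mean()
    return out


def generate_gaze(manifest: SceneManifest, params: PhenotypeParams,
                  sampling_rate: float = 300.0,
                  face_masks: np.ndarray | None = None,
                  subject_id: str = "S0") -> "pd.DataFrame":
    """Simulate one subject's raw gaze stream over the whole stimulus.

    One sample per tick at ``sampling_rate`` Hz (default the 300 Hz of the
    reference eye tracker) minus dropout. Per sample the
    geometric half is chosen with probability ``p_geometric``; within the
    chosen half the sample is uniform noise with probability
    ``uniform_noise``, otherwise a Gaussian around the face centroid (on the
    biological half, with probability ``face_attraction``) or around the
    half's center, clipped to the half. Columns follow the gaze TSV dialect:
    subject_id, timestamp_ms, gaze_x_px, gaze_y_px, validity.
    """
    import pandas as pd

    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    h, w = manifest.screen_size
    duration_ms = manifest.n_frames / manifest.fps * 1000.0
    rng = np.random.default_rng(params.seed)
    ts = np.arange(0.0, duration_ms, 1000.0 / sampling_rate)
    keep = rng.random(ts.size) >= params.dropout_rate
    ts = ts[keep]

    centroids = face_centroids(face_masks) if face_masks is not None else None

    rows = np.empty(ts.size)
    cols = np.empty(ts.size)
    frame_idx = np.minimum((ts / 1000.0 * manifest.fps).astype(int), manifest.n_frames - 1)
    seg_sides = np.array([manifest.side_of_frame(f) == "left" for f in frame_idx])  # bio on left?
    on_geo = rng.random(ts.size) < params.p_geometric
    use_noise = rng.random(ts.size) < params.uniform_noise
    to_face = rng.random(ts.size) < params.face_attraction

    r0, r1, c0, c1 = _content_box(h, w)
    mid = (c0 + c1) // 2
    for i in range(ts.size):
        bio_left = seg_sides[i]
        geo_half = (c0, mid) if not bio_left else (mid, c1)
        bio_half = (mid, c1) if not bio_left else (c0, mid)
        lo, hi = geo_half if on_geo[i] else bio_half
        if use_noise[i]:
            rows[i] = rng.uniform(r0, r1)
            cols[i] = rng.uniform(lo, hi)
            continue
        target = None
        if (not on_geo[i]) and to_face[i] and centroids is not None:
            cen = centroids[frame_idx[i]]
            if np.isfinite(cen).all():
                target = cen
        if target is None:
            target = ((r0 + r1) / 2.0, (lo + hi) / 2.0)
        sig = params.center_bias_sigma
        rows[i] = np.clip(rng.normal(target[0], sig), r0, r1 - 1)
        cols[i] = np.clip(rng.normal(target[1], sig), lo, hi - 1)

    return pd.DataFrame({
        "subject_id": subject_id,
        "timestamp_ms": ts,
        "gaze_x_px": cols,
        "gaze_y_px": rows,
        "validity": np.ones(ts.size, dtype=int),
    })


def write_fixtures(outdir, manifest: SceneManifest | None = None, seed: int = 0,
                   n_subjects: int = 2, params: PhenotypeParams | None = None,
                   sampling_rate: float = 300.0) -> dict:
    """Write a complete on-disk fixture set (frames, masks, manifest, gaze TSVs).

    Files round-trip through :mod:`gazevam.io` readers. Returns a dict of the
    written paths. ``outdir`` must already exist.
    """
    from . import io as gio

    outdir = Path(outdir)
    if not outdir.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {outdir}")
    manifest = manifest or default_manifest(n_segments=3, segment_seconds=3.0, fps=10.0,
                                            screen_size=(108, 192))
    params = params or PhenotypeParams(seed=seed)
    frames, masks = generate_stimulus(manifest, seed=seed)

    paths = {}
    paths["manifest"] = gio.write_manifest(outdir / "manifest.yaml", manifest)
    paths["frames"] = gio.write_frames(outdir / "frames", frames)
    for k in MASK_KEYS:
        paths[f"mask_{k}"] = gio.write_frames(outdir / f"mask_{k}",
                                              masks[k].astype(np.uint8) * 255)
    gaze_paths = []
    for s in range(n_subjects):
        p = dataclasses.replace(params, seed=params.seed + s)
        df = generate_gaze(manifest, p, sampling_rate, masks["face"], subject_id=f"S{s}")
        gaze_paths.append(gio.write_gaze_tsv(outdir / f"gaze_S{s}.tsv", df))
    paths["gaze"] = gaze_paths
    return paths
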