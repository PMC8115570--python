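"""End-to-end orchestration: stimulus -> features -> cross-validated diagnosis.

`prepare_stimulus` runs the frame side of the method once (preprocess, pick
held-out diagnosis frames, aggregate the learning frames, stream per-frame
feature stacks into per-frameset means), producing a StimulusBundle that is
independent of subjects and can be reused across cohorts and folds.
`run_synthetic_crossval` wraps the whole study on a synthetic cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .aggregation import AggregationConfig, FrameSet, aggregate_frames
from .diagnosis import CASE, CONTROL, EvalReport, crossval
from .features import FeatureStack, FrameContext, extract_feature_stack
from .preprocess import FrameSequence, GazeStream, map_gaze, preprocess_frames
from .synthetic import PhenotypeParams, SceneManifest, default_manifest, generate_gaze, generate_stimulus
from .vam import TrainConfig

# reference synthetic phenotypes: the preferential-looking contrast. The two
# groups differ only in the geometric-side preference, keeping the within-side
# gaze structure mirror-symmetric between groups (so neither group's saliency
# map is systematically larger than the other's).
CASE_PARAMS = PhenotypeParams(p_geometric=0.8)
CONTROL_PARAMS = PhenotypeParams(p_geometric=0.2)


@dataclass
class StimulusBundle:
    """Subject-independent products of one stimulus video."""

    sequence: FrameSequence
    masks: dict[str, np.ndarray] | None
    crop_box: tuple[int, int, int, int]
    original_screen: tuple[int, int]
    framesets: list[FrameSet]                  # over learning frames (seq positions)
    frameset_stacks: list[FeatureStack]
    diag_frames: list[int]                     # seq positions held out for diagnosis
    diag_stacks: list[FeatureStack]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.sequence.frame_shape


def choose_diagnosis_frames(manifest: SceneManifest, n_diag: int, seed: int = 0) -> np.ndarray:
    """Sample ``n_diag`` frame positions spread across segments (seeded).

    Quotas per segment are proportional to segment length (largest
    remainder); within a segment frames are drawn uniformly without
    replacement.
    """
    lens = np.array([s.n_frames for s in manifest.segments], dtype=float)
    total = int(lens.sum())
    if n_diag > total:
        raise ValueError(f"cannot hold out {n_diag} of {total} frames")
    exact = n_diag * lens / lens.sum()
    quota = np.floor(exact).astype(int)
    rem = n_diag - quota.sum()
    for i in np.argsort(-(exact - quota))[:rem]:
        quota[i] += 1
    rng = np.random.default_rng(seed)
    picks = []
    for seg, q in zip(manifest.segments, quota):
        if q:
            picks.append(np.sort(rng.choice(np.arange(seg.start, seg.end), q, replace=False)))
    return np.sort(np.concatenate(picks)) if picks else np.array([], dtype=int)


def _forced_boundaries(learn_pos: np.ndarray, seq: FrameSequence) -> np.ndarray:
    """Positions (within the learning subsequence) where a frameset must
    close: non-adjacent frames (held-out or transition gaps) or a segment
    change."""
    src = seq.source_indices if seq.source_indices is not None else np.arange(seq.count)
    segs = np.array([seq.manifest.segment_of_frame(int(p)) for p in learn_pos])
    b = []
    for i in range(1, len(learn_pos)):
        if learn_pos[i] != learn_pos[i - 1] + 1 or \
           src[learn_pos[i]] != src[learn_pos[i - 1]] + 1 or \
           segs[i] != segs[i - 1]:
            b.append(i)
    return np.array(b, dtype=int)


def prepare_stimulus(frames: np.ndarray, manifest: SceneManifest,
                     masks: dict[str, np.ndarray] | None = None,
                     n_diag_frames: int = 50, seed: int = 0,
                     agg_cfg: AggregationConfig = AggregationConfig(),
                     max_framesets: int | None = None,
                     detectors: dict | None = None) -> StimulusBundle:
    """Preprocess a stimulus and compute everything gaze-independent.

    Feature stacks are computed in one streaming pass: held-out diagnosis
    frames keep their full per-frame stack; learning frames accumulate into
    their frameset's running mean. ``max_framesets`` optionally caps the
    number of training framesets (evenly subsampled) to bound training cost.
    """
    seq, small_masks, box = preprocess_frames(frames, manifest, masks)
    diag = choose_diagnosis_frames(seq.manifest, n_diag_frames, seed=seed)
    diag_set = set(int(d) for d in diag)
    learn_pos = np.array([p for p in range(seq.count) if p not in diag_set])

    if len(learn_pos):
        bounds = _forced_boundaries(learn_pos, seq)
        raw_sets = aggregate_frames(seq.frames[learn_pos], cfg=agg_cfg, boundaries=bounds)
        framesets = [FrameSet([int(learn_pos[i]) for i in fs.member_frame_indices],
                              fs.mean_frame, fs.motion_to_next) for fs in raw_sets]
    else:
        framesets = []
    if max_framesets is not None and len(framesets) > max_framesets:
        keep = np.unique(np.linspace(0, len(framesets) - 1, max_framesets).round().astype(int))
        framesets = [framesets[i] for i in keep]

    owner = {}
    for k, fs in enumerate(framesets):
        for p in fs.member_frame_indices:
            owner[p] = k

    src = seq.source_indices if seq.source_indices is not None else np.arange(seq.count)
    sums: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    diag_stacks_by_pos: dict[int, FeatureStack] = {}
    for p in range(seq.count):
        if p not in owner and p not in diag_set:
            continue
        prev = seq.frames[p - 1] if p > 0 and src[p] == src[p - 1] + 1 else None
        frame_masks = None
        if small_masks is not None:
            frame_masks = {k: v[p] for k, v in small_masks.items()}
        ctx = FrameContext(bio_side=seq.manifest.side_of_frame(p), prev_frame=prev,
                           masks=frame_masks, detectors=detectors, frame_id=p)
        stack = extract_feature_stack(seq.frames[p], ctx)
        if p in diag_set:
            diag_stacks_by_pos[p] = stack
        else:
            k = owner[p]
            if k in sums:
                sums[k] += stack.channels
                counts[k] += 1
            else:
                sums[k] = stack.channels.astype(np.float64)
                counts[k] = 1

    frameset_stacks = [FeatureStack((sums[k] / counts[k]).astype(np.float32))
                       for k in range(len(framesets))]
    diag_list = [int(d) for d in diag]
    diag_stacks = [diag_stacks_by_pos[p] for p in diag_list]
    return StimulusBundle(seq, small_masks, box, manifest.screen_size,
                          framesets, frameset_stacks, diag_list, diag_stacks)


def map_subject(bundle: StimulusBundle, raw_df) -> GazeStream:
    """Map one subject's raw gaze TSV frame into the bundle's pixel grid."""
    seq = bundle.sequence
    return map_gaze(raw_df, bundle.original_screen, bundle.crop_box,
                    seq.frame_times, seq.manifest.fps,
                    target_shape=seq.frame_shape,
                    source_indices=seq.source_indices)


def simulate_cohort(bundle: StimulusBundle, manifest: SceneManifest,
                    face_masks: np.ndarray | None,
                    n_per_group: int = 20,
                    case_params: PhenotypeParams = CASE_PARAMS,
                    control_params: PhenotypeParams = CONTROL_PARAMS,
                    sampling_rate: float = 300.0, seed: int = 0):
    """Generate and map a labeled synthetic cohort against a prepared stimulus."""
    streams: dict[str, GazeStream] = {}
    labels: dict[str, str] = {}
    for g, (label, base) in enumerate(((CASE, case_params), (CONTROL, control_params))):
        for i in range(n_per_group):
            sid = f"{label}_{i:02d}"
            p = dataclasses.replace(base, seed=seed * 100003 + g * 1009 + i)
            df = generate_gaze(manifest, p, sampling_rate, face_masks, subject_id=sid)
            streams[sid] = map_subject(bundle, df)
            labels[sid] = label
    return streams, labels


def run_synthetic_crossval(n_per_group: int = 20,
                           case_params: PhenotypeParams = CASE_PARAMS,
                           control_params: PhenotypeParams = CONTROL_PARAMS,
                           manifest: SceneManifest | None = None,
                           n_diag_frames: int = 50, k: int = 5, seed: int = 0,
                           sampling_rate: float = 300.0,
                           train_cfg: TrainConfig | None = None,
                           max_framesets: int | None = 12,
                           threshold_mode: str = "test",
                           dilation_radius: int | None = None,
                           bundle: StimulusBundle | None = None,
                           face_masks: np.ndarray | None = None) -> EvalReport:
    """The whole study on a synthetic cohort: stimulus, cohort, k-fold CV.

    The default training configuration caps epochs at 150 — the pixel task on
    the synthetic stimulus converges well before that, and it keeps a full
    5-fold run at desk scale. Pass a prepared ``bundle`` plus the raw
    ``face_masks`` to amortize stimulus rendering and feature extraction
    across runs (e.g. comparing cohorts on one stimulus).
    """
    manifest = manifest or default_manifest()
    if bundle is None:
        frames, masks = generate_stimulus(manifest, seed=seed)
        bundle = prepare_stimulus(frames, manifest, masks,
                                  n_diag_frames=n_diag_frames, seed=seed,
                                  max_framesets=max_framesets)
        face_masks = masks["face"]
    streams, labels = simulate_cohort(bundle, manifest, face_masks, n_per_group,
                                      case_params, control_params,
                                      sampling_rate, seed)
    cfg = train_cfg or TrainConfig(max_epochs=150, seed=seed)
    from .diagnosis import DEFAULT_DILATION
    dil = DEFAULT_DILATION if dilation_radius is None else dilation_radius
    return crossval(streams, labels, bundle.framesets, bundle.frameset_stacks,
                    bundle.diag_frames, bundle.diag_stacks, bundle.frame_shape,
                    k=k, train_cfg=cfg, seed=seed, threshold_mode=threshold_mode,
                    dilation_radius=dil)
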