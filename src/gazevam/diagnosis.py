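"""Diagnosis phase: map matching, per-frame voting, ROC/Youden, subject CV.

For every held-out diagnosis frame, the subject's binary fixation map is
compared against each group's binary saliency map by counting positions with
equal bits (matches). The more similar group earns the frame's vote; a
subject is classified as case when their case-vote count reaches a
threshold, chosen by the Youden index on the ROC built by sweeping every
integer vote threshold. Evaluation is subject-wise k-fold cross-validation:
VAMs are trained on the training subjects and non-diagnosis frames only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fixation import IndividualFixationMap, group_fixation_map, individual_fixation_map, select_coordinates
from .features import FeatureStack, build_training_vectors
from .vam import TrainConfig, binary_saliency_map, train_vam

CASE = "case"
CONTROL = "control"


@dataclass
class VoteRecord:
    subject_id: str
    votes: list[str]              # per-frame: CASE / CONTROL / "tie"
    case_vote_count: int
    n_frames: int

    def __post_init__(self):
        if self.case_vote_count > self.n_frames:
            raise ValueError("more case votes than frames")


@dataclass
class FoldResult:
    test_subjects: list[str]
    counts: np.ndarray
    labels: np.ndarray            # 1 = case
    threshold: int
    precision: float
    sensitivity: float
    specificity: float
    auc: float
    roc: tuple[np.ndarray, np.ndarray, np.ndarray]  # thresholds, sens, spec
    n_framesets_used: int = 0
    n_framesets_skipped: int = 0


@dataclass
class EvalReport:
    folds: list[FoldResult]
    n_diag_frames: int

    def _mean(self, attr):
        return float(np.mean([getattr(f, attr) for f in self.folds]))

    @property
    def mean_auc(self):
        return self._mean("auc")

    @property
    def mean_precision(self):
        return self._mean("precision")

    @property
    def mean_sensitivity(self):
        return self._mean("sensitivity")

    @property
    def mean_specificity(self):
        return self._mean("specificity")

    @property
    def pooled_counts(self):
        return np.concatenate([f.counts for f in self.folds])

    @property
    def pooled_labels(self):
        return np.concatenate([f.labels for f in self.folds])

    @property
    def pooled_auc(self):
        _, _, _, auc = roc_and_auc(self.pooled_counts, self.pooled_labels, self.n_diag_frames)
        return auc

    def summary(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "pooled_auc": self.pooled_auc,
            "mean_precision": self.mean_precision,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "thresholds": [f.threshold for f in self.folds],
            "n_diag_frames": self.n_diag_frames,
        }

    def save(self, outdir) -> "Path":
        """Write the report: summary JSON, per-subject vote counts and
        per-fold ROC points as tab-delimited text."""
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(json.dumps(self.summary(), indent=1))
        with open(out / "votes.tsv", "w") as f:
            f.write("fold\tsubject_id\tlabel\tcase_votes\n")
            for i, fold in enumerate(self.folds):
                for sid, lab, c in zip(fold.test_subjects, fold.labels, fold.counts):
                    f.write(f"{i}\t{sid}\t{int(lab)}\t{int(c)}\n")
        with open(out / "roc.tsv", "w") as f:
            f.write("fold\tthreshold\tsensitivity\tspecificity\n")
            for i, fold in enumerate(self.folds):
                for t, se, sp in zip(*fold.roc):
                    f.write(f"{i}\t{int(t)}\t{se:.6f}\t{sp:.6f}\n")
        return out


def similarity(fix: IndividualFixationMap | np.ndarray, sal: np.ndarray) -> int:
    """Number of positions where fixation and saliency maps agree (0..H*W)."""
    f = fix.bits if isinstance(fix, IndividualFixationMap) else np.asarray(fix)
    s = np.asarray(sal)
    if f.shape != s.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {s.shape}")
    return int(np.count_nonzero(f == s))


def frame_vote(fix, sal_case: np.ndarray, sal_control: np.ndarray) -> str:
    """Vote for the group whose saliency map matches the fixation map better;
    equal similarity is a tie, resolved conservatively to the control group."""
    sc = similarity(fix, sal_case)
    st = similarity(fix, sal_control)
    if sc > st:
        return CASE
    return CONTROL if st > sc else "tie"


def classify_subject(record: VoteRecord, vote_threshold: int) -> str:
    """Case iff the case-vote count reaches the threshold."""
    if not 0 <= vote_threshold <= record.n_frames:
        raise ValueError("threshold must be in [0, n_frames]")
    return CASE if record.case_vote_count >= vote_threshold else CONTROL


def roc_and_auc(counts: np.ndarray, labels: np.ndarray, n_frames: int):
    """ROC over every integer vote threshold, plus trapezoidal AUC.

    ``labels`` are 1 for case. Thresholds run 0..n_frames+1 so both ROC
    endpoints (all-case, all-control) are present. Returns
    ``(thresholds, sensitivity, specificity, auc)``.
    """
    counts = np.asarray(counts)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both classes present")
    thresholds = np.arange(0, n_frames + 2)
    sens = np.array([(counts[labels] >= t).mean() for t in thresholds])
    spec = np.array([(counts[~labels] < t).mean() for t in thresholds])
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # fpr ascending, ties by sens ascending
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return thresholds, sens, spec, auc


def youden_threshold(thresholds: np.ndarray, sens: np.ndarray, spec: np.ndarray) -> int:
    """Threshold maximizing J = sensitivity + specificity - 1 (ties: smallest)."""
    if len(thresholds) < 2:
        raise ValueError("need at least two thresholds")
    J = np.asarray(sens) + np.asarray(spec) - 1.0
    return int(np.asarray(thresholds)[int(np.argmax(J))])


def _metrics_at(counts, labels, t):
    pred = counts >= t
    labels = labels.astype(bool)
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    return precision, sensitivity, specificity


DEFAULT_DILATION = 8  # px; ~1 degree of visual angle on the 200x350 grid,
                      # the foveal region a raw gaze sample actually covers


def subject_votes(stream, diag_frames, sal_case: list[np.ndarray],
                  sal_control: list[np.ndarray], shape,
                  dilation_radius: int = DEFAULT_DILATION) -> VoteRecord:
    """Vote over all diagnosis frames for one subject's mapped gaze stream.

    The subject's per-frame hit map is dilated by ``dilation_radius`` before
    matching, marking the foveal neighbourhood of each raw sample rather than
    a single pixel; radius 0 reproduces the bare binarized-hits comparison.
    """
    votes = []
    for j, f in enumerate(diag_frames):
        fix = individual_fixation_map(stream, f, shape=shape,
                                      dilation_radius=dilation_radius)
        votes.append(frame_vote(fix, sal_case[j], sal_control[j]))
    return VoteRecord(stream.subject_id, votes, votes.count(CASE), len(diag_frames))


def train_group_vam(group_streams, framesets, frameset_stacks, cfg, seed,
                     n_pos, n_neg, feature_indices, group):
    """Fixation maps -> coordinates -> vectors -> network, over all framesets.

    Framesets whose map cannot supply the required nonzero/zero cells are
    skipped (short sets under sparse gaze); at least one must survive.
    """
    from .aggregation import aggregate_gaze

    per_set = aggregate_gaze(group_streams, framesets)
    Xs, ys = [], []
    used = skipped = 0
    for k, fs in enumerate(framesets):
        fmap = group_fixation_map(per_set[k], k, group)
        try:
            sample = select_coordinates(fmap, n_pos=n_pos, n_neg=n_neg,
                                        seed=seed + k)
        except ValueError:
            skipped += 1
            continue
        X, y = build_training_vectors(frameset_stacks[k], sample)
        Xs.append(X)
        ys.append(y)
        used += 1
    if not Xs:
        raise ValueError(f"no frameset produced a usable fixation map for group {group!r}")
    X = np.concatenate(Xs)
    y = np.concatenate(ys)
    if feature_indices is not None:
        X = X[:, feature_indices]
    model = train_vam(X, y, cfg, group=group, feature_indices=feature_indices)
    return model, used, skipped


def crossval(streams: dict[str, "GazeStream"], labels: dict[str, str],
             framesets, frameset_stacks: list[FeatureStack],
             diag_frames, diag_stacks: list[FeatureStack],
             frame_shape: tuple[int, int],
             k: int = 5, train_cfg: TrainConfig = TrainConfig(),
             n_pos: int = 350, n_neg: int = 350, seed: int = 0,
             feature_indices: np.ndarray | None = None,
             threshold_mode: str = "test",
             dilation_radius: int = DEFAULT_DILATION) -> EvalReport:
    """Subject-wise stratified k-fold evaluation of the full two-VAM pipeline.

    Per fold: both groups' VAMs are trained on the training subjects' pooled
    gaze over the learning framesets; the held-out subjects are classified on
    the diagnosis frames; the vote threshold is chosen by Youden on the test
    fold's ROC (``threshold_mode="test"``, the reference protocol, optimistic
    by construction) or on the training subjects' ROC (``"train"``, the
    honest nested variant).

    ``labels`` maps subject_id to ``"case"``/``"control"``; each training
    fold must contain both groups.
    """
    from sklearn.model_selection import StratifiedKFold

    if threshold_mode not in ("test", "train"):
        raise ValueError("threshold_mode must be 'test' or 'train'")
    sids = sorted(streams)
    y_all = np.array([1 if labels[s] == CASE else 0 for s in sids])
    if y_all.all() or not y_all.any():
        raise ValueError("need both case and control subjects")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for fold_i, (tr, te) in enumerate(skf.split(sids, y_all)):
        tr_ids = [sids[i] for i in tr]
        te_ids = [sids[i] for i in te]
        if len({labels[s] for s in tr_ids}) < 2:
            raise ValueError(f"fold {fold_i}: a class is absent from the training split")

        models = {}
        used = skipped = 0
        for gi, group in enumerate((CASE, CONTROL)):
            gstreams = [streams[s] for s in tr_ids if labels[s] == group]
            m, u, sk = train_group_vam(
                gstreams, framesets, frameset_stacks, train_cfg,
                seed=seed * 10007 + fold_i * 101 + gi * 7919,
                n_pos=n_pos, n_neg=n_neg,
                feature_indices=feature_indices, group=group)
            models[group] = m
            used, skipped = used + u, skipped + sk

        sal_case = [binary_saliency_map(models[CASE], st) for st in diag_stacks]
        sal_control = [binary_saliency_map(models[CONTROL], st) for st in diag_stacks]

        def count_votes(ids):
            recs = [subject_votes(streams[s], diag_frames, sal_case, sal_control,
                                  frame_shape, dilation_radius) for s in ids]
            return np.array([r.case_vote_count for r in recs])

        counts = count_votes(te_ids)
        y_te = np.array([1 if labels[s] == CASE else 0 for s in te_ids])
        n_frames = len(diag_frames)
        thr, sens, spec, auc = roc_and_auc(counts, y_te, n_frames)
        if threshold_mode == "train":
            c_tr = count_votes(tr_ids)
            y_tr = np.array([1 if labels[s] == CASE else 0 for s in tr_ids])
            t_tr, s_tr, p_tr, _ = roc_and_auc(c_tr, y_tr, n_frames)
            t_star = youden_threshold(t_tr, s_tr, p_tr)
        else:
            t_star = youden_threshold(thr, sens, spec)
        precision, sensitivity, specificity = _metrics_at(counts, y_te, t_star)
        folds.append(FoldResult(te_ids, counts, y_te, t_star, precision,
                                sensitivity, specificity, auc, (thr, sens, spec),
                                n_framesets_used=used, n_framesets_skipped=skipped))
    return EvalReport(folds, len(diag_frames))
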