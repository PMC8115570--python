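"""Map matching, voting, ROC/Youden and the cross-validation harness."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from gazevam.diagnosis import (CASE, CONTROL, EvalReport, FoldResult, VoteRecord, classify_subject,
                               crossval, frame_vote, roc_and_auc, similarity,
                               youden_threshold)
from gazevam.fixation import IndividualFixationMap
from gazevam.vam import TrainConfig


class TestSimilarity:
    def test_identical_maps_full_agreement(self):
        m = (np.random.default_rng(0).random((200, 350)) > 0.5).astype(np.uint8)
        assert similarity(m, m) == 70000  # every position of a 200x350 frame

    def test_complementary_maps_zero(self):
        m = (np.random.default_rng(1).random((50, 60)) > 0.5).astype(np.uint8)
        assert similarity(m, 1 - m) == 0

    def test_random_pair_matches_double_loop_oracle(self, rng):
        a = rng.integers(0, 2, (4, 4)).astype(np.uint8)
        b = rng.integers(0, 2, (4, 4)).astype(np.uint8)
        count = 0
        for i in range(4):
            for j in range(4):
                count += int(a[i, j] == b[i, j])
        assert similarity(a, b) == count

    def test_complement_conservation(self, rng):
        for _ in range(5):
            a = rng.integers(0, 2, (20, 35)).astype(np.uint8)
            s = rng.integers(0, 2, (20, 35)).astype(np.uint8)
            assert similarity(a, s) + similarity(a, 1 - s) == 20 * 35

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            similarity(np.zeros((2, 2)), np.zeros((3, 2)))

    def test_accepts_fixation_map_object(self):
        fix = IndividualFixationMap(np.ones((3, 3), np.uint8), "s", 0)
        assert similarity(fix, np.ones((3, 3), np.uint8)) == 9


class TestVoting:
    def test_higher_similarity_wins(self):
        fix = np.zeros((4, 4), np.uint8)
        fix[0, 0] = 1
        sal_case = fix.copy()          # perfect match
        sal_ctrl = 1 - fix             # complementary
        assert frame_vote(fix, sal_case, sal_ctrl) == CASE
        assert frame_vote(fix, sal_ctrl, sal_case) == CONTROL

    def test_tie_resolves_to_control(self):
        fix = np.zeros((2, 2), np.uint8)
        sal = np.zeros((2, 2), np.uint8)
        assert frame_vote(fix, sal, sal.copy()) == "tie"
        rec = VoteRecord("s", ["tie", "tie"], 0, 2)
        assert classify_subject(rec, 1) == CONTROL

    def test_threshold_rule(self):
        assert classify_subject(VoteRecord("s", [], 28, 50), 28) == CASE
        assert classify_subject(VoteRecord("s", [], 27, 50), 28) == CONTROL
        assert classify_subject(VoteRecord("s", [], 0, 50), 1) == CONTROL

    def test_vote_count_bounded(self):
        with pytest.raises(ValueError):
            VoteRecord("s", [], 6, 5)


class TestROC:
    def test_perfect_separation_auc_one(self):
        counts = np.array([40, 45, 10, 5])
        labels = np.array([1, 1, 0, 0])
        *_, auc = roc_and_auc(counts, labels, 50)
        assert auc == 1.0

    def test_exchangeable_counts_auc_half(self):
        counts = np.array([20, 20, 20, 20])
        *_, auc = roc_and_auc(counts, np.array([1, 0, 1, 0]), 50)
        assert auc == 0.5

    def test_matches_mann_whitney_oracle(self, rng):
        for _ in range(20):
            c1 = rng.integers(0, 51, 3)
            c0 = rng.integers(0, 51, 3)
            counts = np.concatenate([c1, c0])
            labels = np.array([1] * 3 + [0] * 3)
            *_, auc = roc_and_auc(counts, labels, 50)
            u = mannwhitneyu(c1, c0).statistic
            assert auc == pytest.approx(u / 9)

    def test_monotone_sensitivity_and_specificity(self, rng):
        counts = rng.integers(0, 51, 12)
        labels = np.array([1] * 6 + [0] * 6)
        _, sens, spec, _ = roc_and_auc(counts, labels, 50)
        assert (np.diff(sens) <= 1e-12).all()
        assert (np.diff(spec) >= -1e-12).all()

    def test_label_swap_flips_auc(self, rng):
        counts = rng.integers(0, 51, 10)
        labels = np.array([1] * 5 + [0] * 5)
        *_, auc = roc_and_auc(counts, labels, 50)
        *_, swapped = roc_and_auc(counts, 1 - labels, 50)
        assert swapped == pytest.approx(1.0 - auc)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_and_auc(np.array([1, 2]), np.array([1, 1]), 50)


class TestYouden:
    def test_perfect_separation_returns_split_point(self):
        counts = np.array([40, 45, 10, 5])
        labels = np.array([1, 1, 0, 0])
        t, sens, spec, _ = roc_and_auc(counts, labels, 50)
        t_star = youden_threshold(t, sens, spec)
        J = sens + spec - 1
        assert J[t_star] == pytest.approx(1.0)
        assert 10 < t_star <= 40

    def test_flat_J_returns_smallest(self):
        t = np.array([0, 1, 2, 3])
        sens = np.array([1.0, 1.0, 1.0, 1.0])
        spec = np.array([0.0, 0.0, 0.0, 0.0])
        assert youden_threshold(t, sens, spec) == 0

    def test_matches_exhaustive_scan(self, rng):
        counts = rng.integers(0, 11, 8)
        labels = np.array([1] * 4 + [0] * 4)
        t, sens, spec, _ = roc_and_auc(counts, labels, 10)
        best, best_j = None, -np.inf
        for tt in range(0, 12):
            s = (counts[labels == 1] >= tt).mean()
            p = (counts[labels == 0] < tt).mean()
            if s + p - 1 > best_j + 1e-12:
                best, best_j = tt, s + p - 1
        assert youden_threshold(t, sens, spec) == best


class TestCrossval:
    def test_folds_partition_subjects(self, tiny_bundle, tiny_cohort):
        streams, labels = tiny_cohort
        rep = crossval(streams, labels, tiny_bundle.framesets,
                       tiny_bundle.frameset_stacks, tiny_bundle.diag_frames,
                       tiny_bundle.diag_stacks, tiny_bundle.frame_shape,
                       k=3, train_cfg=TrainConfig(max_epochs=5, seed=0), seed=0)
        seen = [s for f in rep.folds for s in f.test_subjects]
        assert sorted(seen) == sorted(streams)          # each subject once
        assert all(len(f.test_subjects) == 4 for f in rep.folds)  # 12/3
        assert rep.n_diag_frames == len(tiny_bundle.diag_frames)
        s = rep.summary()
        assert 0.0 <= s["mean_auc"] <= 1.0

    def test_single_class_cohort_rejected(self, tiny_bundle, tiny_cohort):
        streams, labels = tiny_cohort
        bad = {s: CASE for s in labels}
        with pytest.raises(ValueError, match="both"):
            crossval(streams, bad, tiny_bundle.framesets,
                     tiny_bundle.frameset_stacks, tiny_bundle.diag_frames,
                     tiny_bundle.diag_stacks, tiny_bundle.frame_shape, k=3)


def test_report_save_writes_summary_votes_and_roc(tmp_path):
    fold = FoldResult(["a", "b"], np.array([40, 5]), np.array([1, 0]), 20,
                      1.0, 1.0, 1.0, 1.0,
                      (np.array([0, 1]), np.array([1.0, 1.0]), np.array([0.0, 1.0])))
    rep = EvalReport([fold], 50)
    out = rep.save(tmp_path / "run")
    assert (out / "summary.json").exists()
    votes = (out / "votes.tsv").read_text().strip().splitlines()
    assert votes[0].startswith("fold") and len(votes) == 3
    assert (out / "roc.tsv").read_text().count("\n") == 3
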