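"""Frame targets, confusion matrices, agreement statistics, and IAR."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import cohen_kappa_score

from maiju.annotations import (
    AnnotationSet,
    CompoundConfusion,
    cohen_kappa_from_confusion,
    compound_confusion,
    fleiss_kappa,
    frames_from_annotations,
    iar_refine,
    per_class_metrics,
    read_annotations,
    write_annotations,
)
from maiju.io import FrameArray
from maiju.taxonomy import FRAME_HOP, FRAME_LEN, SAMPLE_RATE

from conftest import make_recording, truth_annotations


def _frames_for(n_seconds):
    """A FrameArray scaffold (content irrelevant for labeling) spanning
    n_seconds of signal."""
    n_samples = int(n_seconds * SAMPLE_RATE)
    n_frames = (n_samples - FRAME_LEN) // FRAME_HOP + 1
    centers = (np.arange(n_frames) * FRAME_HOP + FRAME_LEN / 2) / SAMPLE_RATE
    return FrameArray(frames=np.zeros((n_frames, FRAME_LEN, 24)),
                      frame_times=centers, t0=0.0)


def _ann(posture_rows):
    rows = np.asarray(posture_rows)
    n_r, n_s = rows.shape
    return AnnotationSet(raters=[f"r{i}" for i in range(n_r)],
                         data={"posture": rows})


class TestFrameLabels:
    def test_unanimous_constant_labels(self):
        ann = _ann(np.full((3, 20), 2))
        fl = frames_from_annotations(ann, _frames_for(20), "posture")
        assert np.all(fl.hard == 2)
        assert not fl.ambiguous.any()
        assert np.allclose(fl.dist[:, 2], 1.0)

    def test_plurality_across_label_change(self):
        # label changes at t=10 s; the frame covering [9.46, 11.77) has
        # ~0.54 s of class 0 and ~1.77 s of class 1 -> plurality class 1
        lab = np.concatenate([np.zeros(10, int), np.ones(10, int)])
        ann = _ann(lab[None, :].repeat(2, axis=0))
        fl = frames_from_annotations(ann, _frames_for(20), "posture")
        starts = (np.arange(fl.n_frames) * FRAME_HOP) / SAMPLE_RATE
        frame = np.flatnonzero((starts < 10) & (starts + FRAME_LEN / SAMPLE_RATE > 10))
        for i in frame:
            span0 = 10 - starts[i]
            span1 = starts[i] + FRAME_LEN / SAMPLE_RATE - 10
            assert fl.hard[i] == (0 if span0 > span1 else 1)

    def test_split_vote_distribution(self):
        rows = np.vstack([np.full(20, 1), np.full(20, 1), np.full(20, 4)])
        fl = frames_from_annotations(_ann(rows), _frames_for(20), "posture")
        assert np.allclose(fl.dist[:, 1], 2 / 3)
        assert np.allclose(fl.dist[:, 4], 1 / 3)
        assert np.all(fl.hard == 1)
        assert fl.ambiguous.all()

    def test_unlabeled_frames_marked(self):
        rows = np.full((2, 20), -1)
        rows[:, :5] = 0
        fl = frames_from_annotations(_ann(rows), _frames_for(20), "posture")
        assert fl.hard[-1] == -1
        assert not fl.valid[-1]


class TestConfusion:
    def test_identical_sequences_diagonal(self):
        seq = np.array([0, 1, 2, 1, 0])
        cm = compound_confusion([(seq, seq)], ["a", "b", "c"])
        assert np.array_equal(cm.counts, np.diag([2, 2, 1]))

    def test_additivity_over_recordings(self):
        rng = np.random.default_rng(0)
        a = (rng.integers(0, 3, 50), rng.integers(0, 3, 50))
        b = (rng.integers(0, 3, 70), rng.integers(0, 3, 70))
        cm_ab = compound_confusion([a, b], ["x", "y", "z"])
        cm_sum = (compound_confusion([a], ["x", "y", "z"])
                  + compound_confusion([b], ["x", "y", "z"]))
        assert np.array_equal(cm_ab.counts, cm_sum.counts)

    def test_manual_tally(self):
        target = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        pred = np.array([0, 0, 1, 1, 1, 1, 1, 0, 0, 0])
        cm = compound_confusion([(target, pred)], ["neg", "pos"])
        assert np.array_equal(cm.counts, [[2, 2], [3, 3]])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            compound_confusion([(np.array([0, 5]), np.array([0, 1]))], ["a", "b"])


class TestKappa:
    def test_perfect_agreement_is_one(self):
        rows = np.tile(np.array([0, 1, 2, 1, 0] * 10), (3, 1))
        assert fleiss_kappa(_ann(rows), track="posture") == pytest.approx(1.0)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(1)
        rows = rng.integers(0, 7, (3, 10_000))
        assert abs(fleiss_kappa(_ann(rows), track="posture")) < 0.05

    def test_worked_table_matches_hand_computation(self):
        # 3 raters x 6 items, 3 categories; oracle computed directly from
        # the defining formulas below.
        rows = np.array([[0, 0, 1, 2, 2, 0],
                         [0, 1, 1, 2, 0, 0],
                         [0, 0, 1, 1, 2, 0]])
        table = np.stack([(rows == c).sum(axis=0) for c in range(3)], axis=1)
        n_rat = 3
        p_i = ((table ** 2).sum(axis=1) - n_rat) / (n_rat * (n_rat - 1))
        p_bar = p_i.mean()
        p_j = table.sum(axis=0) / table.sum()
        p_e = (p_j ** 2).sum()
        expected = (p_bar - p_e) / (1 - p_e)
        assert fleiss_kappa(_ann(rows), track="posture") == pytest.approx(expected)

    def test_confusion_form_matches_sklearn_cohen(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 4, 500)
        b = np.where(rng.random(500) < 0.7, a, rng.integers(0, 4, 500))
        cm = compound_confusion([(a, b)], list("wxyz"))
        assert cohen_kappa_from_confusion(cm) == pytest.approx(
            cohen_kappa_score(a, b))

    def test_single_category_undefined(self):
        rows = np.zeros((3, 50), int)
        with pytest.raises(ValueError, match="undefined"):
            fleiss_kappa(_ann(rows), track="posture")


class TestPerClassMetrics:
    def test_diagonal_matrix_all_ones(self):
        cm = CompoundConfusion(np.diag([5, 3, 7]), ("a", "b", "c"))
        m = per_class_metrics(cm)
        assert m["accuracy"] == 1.0
        for cls in m["classes"].values():
            assert cls["recall"] == cls["precision"] == cls["f1"] == 1.0

    def test_two_class_arithmetic(self):
        cm = CompoundConfusion(np.array([[8, 2], [3, 7]]), ("a", "b"))
        m = per_class_metrics(cm)
        assert m["classes"]["a"]["recall"] == pytest.approx(0.8)
        assert m["classes"]["a"]["precision"] == pytest.approx(8 / 11)
        assert m["accuracy"] == pytest.approx(0.75)

    def test_empty_class_reported_nan(self):
        cm = CompoundConfusion(np.array([[5, 0, 0], [1, 4, 0], [0, 0, 0]]),
                               ("a", "b", "c"))
        m = per_class_metrics(cm)
        assert np.isnan(m["classes"]["c"]["recall"])

    def test_permutation_invariance(self):
        counts = np.array([[8, 2, 1], [3, 7, 0], [2, 2, 6]])
        m1 = per_class_metrics(CompoundConfusion(counts, ("a", "b", "c")))
        perm = [2, 0, 1]
        m2 = per_class_metrics(
            CompoundConfusion(counts[np.ix_(perm, perm)], ("c", "a", "b")))
        assert m1["accuracy"] == pytest.approx(m2["accuracy"])
        for cls in "abc":
            assert m1["classes"][cls] == pytest.approx(m2["classes"][cls])


class TestAnnotationIO:
    def test_round_trip(self, tmp_path):
        _, seq, _ = make_recording(duration_s=60, seed=1)
        ann = truth_annotations(seq, n_raters=3)
        path = write_annotations(ann, tmp_path / "ann.csv")
        back = read_annotations(path)
        for track in ann.data:
            assert np.array_equal(back.data[track], ann.data[track])


class TestIAR:
    @staticmethod
    def _labels(dist, ambiguous=None):
        from maiju.annotations import FrameLabels
        n, k = dist.shape
        hard = np.argmax(dist, axis=1)
        amb = (dist.max(axis=1) < 1.0 - 1e-9) if ambiguous is None else ambiguous
        return FrameLabels(track="posture", hard=hard, dist=dist,
                           unlabeled_frac=np.zeros(n), ambiguous=amb,
                           valid=np.ones(n, bool), n_raters=3)

    def test_alpha_zero_is_identity(self):
        dist = np.array([[1.0, 0.0], [2 / 3, 1 / 3], [0.0, 1.0]])
        res = iar_refine(self._labels(dist), train=lambda t: t, alpha=0.0)
        assert np.allclose(res.targets, dist)
        assert res.iterations == 0

    def test_uncontested_targets_conserved(self):
        rng = np.random.default_rng(3)
        dist = np.eye(3)[rng.integers(0, 3, 50)]
        dist[:10] = [0.5, 0.5, 0.0]  # contested block

        def train(t):
            return np.full_like(t, 1 / 3)

        res = iar_refine(self._labels(dist), train=train, alpha=0.7)
        assert np.allclose(res.targets[10:], dist[10:])
        assert not np.allclose(res.targets[:10], dist[:10])

    def test_no_contested_frames_returns_input(self):
        dist = np.eye(2)[np.array([0, 1, 0, 1])]
        res = iar_refine(self._labels(dist), train=lambda t: t, alpha=0.5)
        assert res.iterations == 0
        assert np.allclose(res.targets, dist)

    def test_refinement_beats_raw_majority_with_bad_rater(self):
        """One systematically deviant rater: IAR targets should sit closer
        (lower cross-entropy) to the ground truth than the raw votes."""
        rng = np.random.default_rng(4)
        n = 600
        truth = rng.integers(0, 2, n)
        feats = truth[:, None] + rng.normal(0, 0.3, (n, 2))  # separable features
        good1 = truth.copy()
        good2 = np.where(rng.random(n) < 0.95, truth, 1 - truth)
        bad = np.where(truth == 0, 1, truth)  # deviant: calls every 0 a 1
        votes = np.stack([good1, good2, bad])
        dist = np.stack([(votes == c).mean(axis=0) for c in (0, 1)], axis=1)
        labels = self._labels(dist)

        def train(t):
            clf = LogisticRegression().fit(feats, np.argmax(t, axis=1))
            return clf.predict_proba(feats)

        res = iar_refine(labels, train=train, alpha=0.5, max_iter=3)
        onehot = np.eye(2)[truth]

        def xent(q):
            return -(onehot * np.log(np.clip(q, 1e-9, 1))).sum(axis=1).mean()

        assert xent(res.targets) < xent(dist)
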