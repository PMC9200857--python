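"""Multi-rater annotations, frame targets, and agreement statistics.

Annotations are per-second categorical labels on three tracks (posture,
movement, carrying) from two or more independent raters. This module maps
them onto 2.3-s analysis frames, compounds confusion matrices across
recordings, computes agreement statistics (Fleiss' kappa in its multi-rater
and two-rater/confusion forms, per-class recall/precision/F1/kappa), and
implements iterative annotation refinement (IAR), which mixes contested
rater labels with a classifier's posterior to obtain more consistent
training targets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss

from .io import FrameArray
from .taxonomy import (
    FRAME_LEN,
    TRACKS,
    UNLABELED,
    UNLABELED_CODE,
    decode,
    encode,
)


@dataclass
class AnnotationSet:
    """Per-rater, per-second labels on the three tracks (integer codes,
    ``-1`` = unlabeled). All raters cover the same time span."""

    raters: list[str]
    #: track -> [n_raters, n_seconds] integer label codes
    data: dict[str, np.ndarray]

    def __post_init__(self):
        if len(self.raters) < 1:
            raise ValueError("at least one rater required")
        spans = {v.shape for v in self.data.values()}
        n_sec = {s[1] for s in spans}
        if len(n_sec) > 1:
            raise ValueError("tracks cover different time spans")
        for track, arr in self.data.items():
            if track not in TRACKS:
                raise ValueError(f"unknown track {track!r}")
            k = len(TRACKS[track])
            if arr.max(initial=-1) >= k or arr.min(initial=0) < -1:
                raise ValueError(f"label code out of range on track {track!r}")

    @property
    def n_raters(self) -> int:
        return len(self.raters)

    @property
    def n_seconds(self) -> int:
        return int(next(iter(self.data.values())).shape[1])


def write_annotations(ann: AnnotationSet, path) -> Path:
    """Write as CSV ``rater,track,start_s,end_s,label`` (half-open
    second intervals, run-length encoded)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rater", "track", "start_s", "end_s", "label"])
        for track, arr in ann.data.items():
            classes = TRACKS[track]
            for r, rater in enumerate(ann.raters):
                lab = arr[r]
                bounds = np.flatnonzero(np.diff(lab)) + 1
                starts = np.concatenate(([0], bounds))
                ends = np.concatenate((bounds, [len(lab)]))
                for s, e in zip(starts, ends):
                    name = (UNLABELED if lab[s] == UNLABELED_CODE
                            else classes[lab[s]])
                    w.writerow([rater, track, int(s), int(e), name])
    return path


def read_annotations(path) -> AnnotationSet:
    """Read the CSV annotation format written by :func:`write_annotations`."""
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            try:
                rows.append((row["rater"], row["track"], int(row["start_s"]),
                             int(row["end_s"]), row["label"]))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"malformed annotation row {i + 2}: {exc}") from exc
    if not rows:
        raise ValueError(f"empty annotation file {path}")
    raters = sorted({r[0] for r in rows})
    n_sec = max(r[3] for r in rows)
    data = {}
    tracks = sorted({r[1] for r in rows})
    for track in tracks:
        if track not in TRACKS:
            raise ValueError(f"unknown track {track!r}")
        arr = np.full((len(raters), n_sec), UNLABELED_CODE, dtype=np.int64)
        data[track] = arr
    for rater, track, s, e, label in rows:
        code = (UNLABELED_CODE if label == UNLABELED
                else encode([label], TRACKS[track])[0])
        data[track][raters.index(rater), s:e] = code
    return AnnotationSet(raters=raters, data=data)


# --------------------------------------------------------------------------
# Frame targets
# --------------------------------------------------------------------------

@dataclass
class FrameLabels:
    """Per-frame targets for one track.

    ``dist`` is the fraction of raters voting each class (rows may sum to
    < 1 when some raters are unlabeled; ``unlabeled_frac`` holds the
    remainder so dist + unlabeled sums to 1). ``hard`` is the across-rater
    majority (-1 where the frame is effectively unlabeled), ``ambiguous``
    flags frames where raters disagree, and ``valid`` marks frames usable
    for training/metrics (more than half of rater-time labeled).
    """

    track: str
    hard: np.ndarray          # [n_frames] int codes, -1 = unlabeled
    dist: np.ndarray          # [n_frames, K] rater vote fractions
    unlabeled_frac: np.ndarray
    ambiguous: np.ndarray     # [n_frames] bool
    valid: np.ndarray         # [n_frames] bool
    n_raters: int = 2

    @property
    def n_frames(self) -> int:
        return int(self.hard.shape[0])

    def normalized_dist(self) -> np.ndarray:
        """Vote distribution renormalized over labeled raters."""
        d = self.dist.copy()
        tot = d.sum(axis=1, keepdims=True)
        np.divide(d, tot, out=d, where=tot > 0)
        return d


def _plurality_label(labels_sec: np.ndarray, start: float, end: float) -> int:
    """Label covering the largest share of [start, end); ties broken by
    the track's fixed class order (lower code wins). Unlabeled time only
    counts if it exceeds half the frame."""
    n_sec = len(labels_sec)
    s0 = max(int(np.floor(start)), 0)
    s1 = min(int(np.ceil(end)), n_sec)
    if s1 <= s0:
        return UNLABELED_CODE
    shares: dict[int, float] = {}
    for s in range(s0, s1):
        ov = min(end, s + 1.0) - max(start, float(s))
        if ov <= 0:
            continue
        lab = int(labels_sec[s])
        shares[lab] = shares.get(lab, 0.0) + ov
    covered = sum(shares.values())
    unl = shares.pop(UNLABELED_CODE, 0.0) + max(0.0, (end - start) - covered)
    if not shares or unl > 0.5 * (end - start):
        return UNLABELED_CODE
    best = min(shares, key=lambda c: (-shares[c], c))
    return best


def frames_from_annotations(ann: AnnotationSet, frames: FrameArray,
                            track: str) -> FrameLabels:
    """Assign each frame a per-rater label by plurality of annotated time
    within the frame interval, compounded across raters into a vote
    distribution with an across-rater majority hard label."""
    classes = TRACKS[track]
    k = len(classes)
    labels = ann.data[track]
    n_frames = frames.n_frames
    frame_len_s = FRAME_LEN / frames.rate
    starts = (frames.frame_times - frames.t0) - frame_len_s / 2.0

    votes = np.full((ann.n_raters, n_frames), UNLABELED_CODE, dtype=np.int64)
    for r in range(ann.n_raters):
        lab = labels[r]
        for i in range(n_frames):
            votes[r, i] = _plurality_label(lab, starts[i], starts[i] + frame_len_s)

    dist = np.zeros((n_frames, k))
    for c in range(k):
        dist[:, c] = (votes == c).mean(axis=0)
    unlabeled = (votes == UNLABELED_CODE).mean(axis=0)
    valid = unlabeled <= 0.5
    hard = np.where(dist.sum(axis=1) > 0, np.argmax(dist, axis=1), UNLABELED_CODE)
    hard = np.where(valid, hard, UNLABELED_CODE)
    ambiguous = np.any(votes != votes[0], axis=0) & valid
    return FrameLabels(track=track, hard=hard.astype(np.int64), dist=dist,
                       unlabeled_frac=unlabeled, ambiguous=ambiguous,
                       valid=valid, n_raters=ann.n_raters)


# --------------------------------------------------------------------------
# Confusion matrices and agreement
# --------------------------------------------------------------------------

@dataclass
class CompoundConfusion:
    """A K x K confusion count matrix summed over recordings / rater pairs
    (rows = target class, columns = predicted class)."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, float)
        if self.counts.shape != (len(self.classes), len(self.classes)):
            raise ValueError("confusion shape does not match class list")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_items(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "CompoundConfusion") -> "CompoundConfusion":
        if self.classes != other.classes:
            raise ValueError("cannot sum confusions over different classes")
        return CompoundConfusion(self.counts + other.counts, self.classes)


def compound_confusion(pairs, classes) -> CompoundConfusion:
    """Sum (target, predicted) label-sequence pairs into one confusion
    matrix. Items where either side is unlabeled (-1) are skipped."""
    classes = tuple(classes)
    k = len(classes)
    counts = np.zeros((k, k))
    for target, pred in pairs:
        target = np.asarray(target)
        pred = np.asarray(pred)
        if target.shape != pred.shape:
            raise ValueError("target/predicted sequences not aligned")
        if (target.max(initial=-1) >= k or pred.max(initial=-1) >= k
                or target.min(initial=0) < -1 or pred.min(initial=0) < -1):
            raise ValueError("unknown class label in sequence")
        m = (target >= 0) & (pred >= 0)
        np.add.at(counts, (target[m], pred[m]), 1)
    return CompoundConfusion(counts=counts, classes=classes)


def cohen_kappa_from_confusion(cm: CompoundConfusion) -> float:
    """Two-rater chance-corrected agreement from a confusion matrix."""
    c = cm.counts
    n = c.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(c) / n
    pe = float((c.sum(axis=1) / n) @ (c.sum(axis=0) / n))
    if pe >= 1.0 - 1e-12:
        raise ValueError("kappa undefined: all items in a single category")
    return float((po - pe) / (1.0 - pe))


def fleiss_kappa(x, track: str | None = None) -> float:
    """Chance-corrected multi-rater agreement.

    Accepts an :class:`AnnotationSet` (with ``track``), in which case the
    standard multi-rater Fleiss' kappa is computed on the item x category
    rater-count table (seconds with any unlabeled rater are dropped), or a
    :class:`CompoundConfusion`, in which case the two-rater
    (Cohen-type chance correction) specialization is returned.
    """
    if isinstance(x, CompoundConfusion):
        return cohen_kappa_from_confusion(x)
    if not isinstance(x, AnnotationSet):
        raise TypeError("expected AnnotationSet or CompoundConfusion")
    if track is None:
        raise ValueError("track required with an AnnotationSet")
    if x.n_raters < 2:
        raise ValueError("Fleiss' kappa requires >= 2 raters")
    labels = x.data[track]
    k = len(TRACKS[track])
    keep = np.all(labels >= 0, axis=0)
    lab = labels[:, keep]
    if lab.shape[1] == 0:
        raise ValueError("no fully-labeled items")
    table = np.stack([(lab == c).sum(axis=0) for c in range(k)], axis=1)
    # chance agreement of 1 (single category everywhere) is undefined
    cat_tot = table.sum(axis=0)
    if np.count_nonzero(cat_tot) < 2:
        raise ValueError("kappa undefined: all items in a single category")
    return float(_sm_fleiss(table, method="fleiss"))


def per_class_metrics(cm: CompoundConfusion) -> dict:
    """Recall, precision, F1 and one-vs-rest kappa per class, plus overall
    accuracy and the unweighted average F1 over defined classes. Metrics of
    empty classes are reported as NaN (undefined), not 0."""
    c = cm.counts
    n = c.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    out: dict = {"classes": {}}
    f1s = []
    for i, name in enumerate(cm.classes):
        tp = c[i, i]
        row = c[i].sum()
        col = c[:, i].sum()
        recall = tp / row if row > 0 else np.nan
        precision = tp / col if col > 0 else np.nan
        if np.isnan(recall) or np.isnan(precision) or (recall + precision) == 0:
            f1 = np.nan
        else:
            f1 = 2 * recall * precision / (recall + precision)
        if row > 0 or col > 0:
            two = np.array([[tp, row - tp], [col - tp, n - row - col + tp]])
            try:
                kap = cohen_kappa_from_confusion(
                    CompoundConfusion(two, (name, "rest")))
            except ValueError:
                kap = np.nan
        else:
            kap = np.nan
        out["classes"][name] = dict(recall=float(recall), precision=float(precision),
                                    f1=float(f1), kappa=float(kap))
        if not np.isnan(f1):
            f1s.append(f1)
    out["accuracy"] = float(np.trace(c) / n)
    out["macro_f1"] = float(np.mean(f1s)) if f1s else np.nan
    return out


# --------------------------------------------------------------------------
# Iterative annotation refinement
# --------------------------------------------------------------------------

@dataclass
class RefinedTargets:
    """Probabilistic frame targets after iterative annotation refinement."""

    targets: np.ndarray        # [n_frames, K], rows sum to 1 (valid frames)
    iterations: int
    altered_fraction: float
    valid: np.ndarray = field(default=None)


def iar_refine(labels: FrameLabels, train, alpha: float = 0.5,
               max_iter: int = 3, tol: float = 0.01) -> RefinedTargets:
    """Iterative annotation refinement.

    Uncontested frames (all raters agree) keep their one-hot targets.
    Contested frames are re-targeted as the renormalized mixture
    ``(1 - alpha) * rater_distribution + alpha * classifier_posterior``,
    where the posterior comes from ``train(targets) -> posterior``
    (a callable that trains a classifier on the current targets and returns
    its per-frame class probabilities). Iteration stops when fewer than
    ``tol`` of the valid frames changed (L1 > 0.01) or after ``max_iter``
    rounds.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    rater = labels.normalized_dist()
    valid = labels.valid & (rater.sum(axis=1) > 0)
    contested = labels.ambiguous & valid
    targets = rater.copy()
    if not contested.any() or alpha == 0.0:
        return RefinedTargets(targets=targets, iterations=0,
                              altered_fraction=0.0, valid=valid)

    altered = 1.0
    it = 0
    while it < max_iter and altered >= tol:
        posterior = np.asarray(train(targets), float)
        if posterior.shape != targets.shape:
            raise ValueError("classifier posterior shape mismatch")
        mixed = (1.0 - alpha) * rater + alpha * posterior
        mixed /= np.clip(mixed.sum(axis=1, keepdims=True), 1e-12, None)
        new = targets.copy()
        new[contested] = mixed[contested]
        delta = np.abs(new - targets).sum(axis=1)
        altered = float((delta[valid] > 0.01).mean())
        targets = new
        it += 1
    return RefinedTargets(targets=targets, iterations=it,
                          altered_fraction=altered, valid=valid)
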