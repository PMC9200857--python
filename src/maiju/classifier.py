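"""Deep motor-ability classification.

A frame-level convolutional encoder fuses the 24-channel signals of each
2.3-s frame into a 160-dimensional latent vector; a dilated temporal
convolution stack models frame-to-frame dynamics and emits per-frame
softmax probabilities for one classification track (posture, movement, or
carrying — the tracks are trained as separate models sharing the same
architecture).

Training uses minibatches of 100 consecutive frames with ADAM
(lr 1e-4, beta1 0.9, beta2 0.999, eps 1e-8), weighted categorical
cross-entropy (inverse-frequency class weights), sample dropout (p = 0.3,
random time samples zeroed) and sensor dropout (p = 0.3, each sensor's six
channels zeroed independently per batch window). 20% of frames are held
out for validation; the epoch with the best validation unweighted-average
F1 is selected.

The full-scale profile (200 epochs, lr 1e-4) matches the reference training
recipe; ``SCALED_PROFILE`` is a faster profile for small synthetic corpora.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .annotations import compound_confusion, per_class_metrics
from .taxonomy import CARRYING, FRAME_LEN

#: Reduced training profile for small synthetic corpora.
SCALED_PROFILE = dict(epochs=12, lr=1e-3)

#: Fixed per-channel input scaling: accelerometers to units of g,
#: gyroscopes to units of a 100 deg/s dynamic range. Keeps all 24 channels
#: at comparable magnitude for the convolutional front end.
INPUT_SCALE = np.tile(np.concatenate([np.full(3, 1.0 / 9.81),
                                      np.full(3, 1.0 / 100.0)]), 4)


def class_weights(targets: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """Inverse-frequency class weights, normalized to mean 1 over the
    classes present. Absent classes get weight NaN (excluded from loss).

    ``targets`` is either an integer label vector (-1 = unlabeled, ignored)
    or a soft [n, K] distribution matrix.
    """
    targets = np.asarray(targets)
    if targets.ndim == 1:
        if n_classes is None:
            n_classes = int(targets.max()) + 1
        lab = targets[targets >= 0]
        freq = np.bincount(lab, minlength=n_classes).astype(float)
        freq /= max(freq.sum(), 1.0)
    else:
        freq = targets.sum(axis=0)
        freq /= max(freq.sum(), 1e-12)
        n_classes = targets.shape[1]
    present = freq > 0
    w = np.full(n_classes, np.nan)
    w[present] = 1.0 / freq[present]
    w[present] /= w[present].mean()
    return w


def _as_soft(y: np.ndarray, n_classes: int) -> tuple[np.ndarray, np.ndarray]:
    """Targets as a soft [n, K] matrix + labeled mask."""
    y = np.asarray(y)
    if y.ndim == 2:
        mask = y.sum(axis=1) > 0
        soft = np.zeros_like(y, dtype=float)
        soft[mask] = y[mask] / y[mask].sum(axis=1, keepdims=True)
        return soft, mask
    mask = y >= 0
    soft = np.zeros((len(y), n_classes))
    soft[mask, y[mask]] = 1.0
    return soft, mask


class MotorClassifier(BaseEstimator, ClassifierMixin):
    """Single-track frame classifier (encoder + temporal model).

    Parameters follow the reference training recipe; see the module
    docstring. ``fit`` takes per-recording lists so that minibatches of
    consecutive frames never straddle recording boundaries.

    Attributes (after fit)
    ----------------------
    classes_ : ndarray of class indices
    history_ : list of per-epoch dicts (loss, val_f1)
    best_epoch_ : epoch selected by validation unweighted-average F1
    """

    def __init__(self, n_classes: int = 7, latent_dim: int = 160,
                 encoder_widths: tuple = (32, 64), temporal_width: int = 64,
                 dilations: tuple = (1, 2, 4, 8), epochs: int = 200,
                 lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, batch_frames: int = 100,
                 sample_dropout: float = 0.3, sensor_dropout: float = 0.3,
                 val_fraction: float = 0.2, seed: int = 0):
        self.n_classes = n_classes
        self.latent_dim = latent_dim
        self.encoder_widths = encoder_widths
        self.temporal_width = temporal_width
        self.dilations = dilations
        self.epochs = epochs
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.batch_frames = batch_frames
        self.sample_dropout = sample_dropout
        self.sensor_dropout = sensor_dropout
        self.val_fraction = val_fraction
        self.seed = seed

    # ---- model construction ----------------------------------------------

    def _build(self, rng: np.random.Generator) -> None:
        self.encoder_ = nn.FrameEncoder(rng, latent_dim=self.latent_dim,
                                        widths=self.encoder_widths)
        self.temporal_ = nn.TemporalClassifier(
            rng, self.latent_dim, self.n_classes,
            width=self.temporal_width, dilations=self.dilations)
        self._params = self.encoder_.parameters() + self.temporal_.parameters()

    def _forward(self, frames: np.ndarray) -> nn.Tensor:
        x = nn.Tensor(frames * INPUT_SCALE)
        z = self.encoder_(x)                       # [B, latent]
        b = z.shape[0]
        logits = self.temporal_(z.reshape(1, b, -1))  # [B, K]
        return logits

    # ---- fitting -----------------------------------------------------------

    def fit(self, X: list, y: list):
        """Fit on per-recording frame arrays.

        X: list of [F_i, 120, 24] arrays; y: list of int label vectors
        (-1 = unlabeled) or soft [F_i, K] target matrices.
        """
        X = [np.asarray(xi, float) for xi in X]
        for xi in X:
            if xi.ndim != 3 or xi.shape[1:] != (FRAME_LEN, 24):
                raise ValueError("frames must be [n, 120, 24]")
        soft, masks = zip(*[_as_soft(yi, self.n_classes) for yi in y])
        all_soft = np.concatenate(soft)
        present = all_soft.sum(axis=0) > 0
        if present.sum() < 2:
            raise ValueError("need >= 2 classes present to train")
        self.classes_ = np.arange(self.n_classes)

        rng = np.random.default_rng(self.seed)
        self._build(rng)

        w_class = class_weights(all_soft)
        w_class = np.nan_to_num(w_class, nan=0.0)

        # frame-level train/validation split over labeled frames
        n_rec = len(X)
        lab_idx = [np.flatnonzero(m) for m in masks]
        val_sets = []
        for li in lab_idx:
            k = int(round(self.val_fraction * len(li)))
            val_sets.append(set(rng.permutation(li)[:k].tolist()))
        train_counts = [len(li) - len(vs) for li, vs in zip(lab_idx, val_sets)]
        total_train = max(sum(train_counts), 1)

        opt = nn.Adam(self._params, lr=self.lr, beta1=self.beta1,
                      beta2=self.beta2, eps=self.eps)
        rec_p = np.array([max(c, 0) for c in train_counts], float)
        rec_p = rec_p / rec_p.sum() if rec_p.sum() > 0 else np.full(n_rec, 1 / n_rec)

        self.history_ = []
        best_state = self.encoder_.state() + self.temporal_.state()
        best_f1, best_epoch = -np.inf, 0
        steps = max(1, total_train // self.batch_frames)

        for epoch in range(self.epochs):
            losses = []
            for _ in range(steps):
                r = int(rng.choice(n_rec, p=rec_p))
                f = X[r].shape[0]
                b = min(self.batch_frames, f)
                start = int(rng.integers(0, f - b + 1))
                window = X[r][start:start + b].copy()

                if self.sample_dropout > 0:
                    drop = rng.random((b, FRAME_LEN)) < self.sample_dropout
                    window[drop] = 0.0
                if self.sensor_dropout > 0:
                    # each sensor's 6 channels zeroed independently per window
                    for s in range(4):
                        if rng.random() < self.sensor_dropout:
                            window[:, :, 6 * s:6 * s + 6] = 0.0

                tgt = soft[r][start:start + b]
                wrow = tgt @ w_class
                in_val = np.fromiter(((start + i) in val_sets[r] for i in range(b)),
                                     bool, count=b)
                wrow = wrow * masks[r][start:start + b] * ~in_val
                if wrow.sum() <= 0:
                    continue
                logits = self._forward(window)
                loss = nn.softmax_cross_entropy(logits, tgt, wrow)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}: {loss.data}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))

            val_f1 = self._validation_f1(X, soft, masks, val_sets)
            self.history_.append(dict(epoch=epoch,
                                      loss=float(np.mean(losses)) if losses else np.nan,
                                      val_f1=val_f1))
            if val_f1 > best_f1:
                best_f1, best_epoch = val_f1, epoch
                best_state = self.encoder_.state() + self.temporal_.state()

        n_enc = len(self.encoder_.parameters())
        self.encoder_.load_state(best_state[:n_enc])
        self.temporal_.load_state(best_state[n_enc:])
        self.best_epoch_ = best_epoch
        self.best_val_f1_ = best_f1 if np.isfinite(best_f1) else np.nan
        return self

    def _validation_f1(self, X, soft, masks, val_sets) -> float:
        pairs = []
        for r, xi in enumerate(X):
            if not val_sets[r]:
                continue
            idx = np.array(sorted(val_sets[r]), int)
            pred = self.predict(xi)
            truth = np.argmax(soft[r], axis=1)
            pairs.append((truth[idx], pred[idx]))
        if not pairs:
            return np.nan
        cm = compound_confusion(pairs, [str(c) for c in range(self.n_classes)])
        return per_class_metrics(cm)["macro_f1"]

    # ---- inference ---------------------------------------------------------

    def predict_proba(self, frames: np.ndarray) -> np.ndarray:
        """Per-frame class probabilities for one recording [F, 120, 24]."""
        frames = np.asarray(frames, float)
        if frames.ndim != 3 or frames.shape[1:] != (FRAME_LEN, 24):
            raise ValueError("frames must be [n, 120, 24]")
        scaled = frames * INPUT_SCALE
        zs = []
        for i in range(0, frames.shape[0], 256):
            z = self.encoder_(nn.Tensor(scaled[i:i + 256]))
            zs.append(z.data)
        z = np.concatenate(zs)
        logits = self.temporal_(nn.Tensor(z[None, :, :]))
        return nn.softmax(logits.data)

    def predict(self, frames: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(frames), axis=1)


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------

def _subject_folds(subjects: list[str], n_folds: int,
                   rng: np.random.Generator) -> list[list[int]]:
    """Partition recording indices into folds at the subject level, so no
    subject appears in both the train and test side of any fold."""
    uniq = sorted(set(subjects))
    order = rng.permutation(len(uniq))
    groups = np.array_split([uniq[i] for i in order], n_folds)
    folds = []
    for g in groups:
        g = set(g.tolist())
        folds.append([i for i, s in enumerate(subjects) if s in g])
    return [f for f in folds if f]


def crossvalidate_tenfold(frames_list: list, targets_list: list,
                          subjects: list[str], classes,
                          clf_params: dict | None = None, n_folds: int = 10,
                          seed: int = 0) -> dict:
    """Recording-level ten-fold cross-validation.

    Recordings are partitioned into ``n_folds`` groups at the subject
    level; each fold is predicted by a model trained on the others. The
    per-fold (target, prediction) pairs are summed into one compounded
    confusion matrix.
    """
    n = len(frames_list)
    if n < n_folds:
        raise ValueError(
            f"only {n} recordings for {n_folds}-fold CV; use LOSO instead")
    rng = np.random.default_rng(seed)
    folds = _subject_folds(list(subjects), n_folds, rng)
    params = dict(n_classes=len(classes), seed=seed)
    params.update(clf_params or {})

    preds: list = [None] * n
    pairs = []
    for fi, test_idx in enumerate(folds):
        train_idx = [i for i in range(n) if i not in test_idx]
        test_subj = {subjects[i] for i in test_idx}
        train_subj = {subjects[i] for i in train_idx}
        assert not (test_subj & train_subj), "subject leakage across folds"
        clf = MotorClassifier(**{**params, "seed": seed + fi})
        clf.fit([frames_list[i] for i in train_idx],
                [targets_list[i] for i in train_idx])
        for i in test_idx:
            p = clf.predict(frames_list[i])
            preds[i] = p
            truth = np.asarray(targets_list[i])
            if truth.ndim == 2:
                truth = np.where(truth.sum(axis=1) > 0,
                                 np.argmax(truth, axis=1), -1)
            pairs.append((truth, p))
    cm = compound_confusion(pairs, classes)
    return dict(predictions=preds, confusion=cm, folds=folds,
                metrics=per_class_metrics(cm))


# --------------------------------------------------------------------------
# Active carrying detection (ACD)
# --------------------------------------------------------------------------

ACTIVE_CARRY_CODE = CARRYING.index("active_carry")
ACD_CLASSES = ("not_carrying", "active_carry")


def collapse_carrying(labels: np.ndarray) -> np.ndarray:
    """5-class carrying labels -> binary: active_carry vs everything else
    (unlabeled -1 preserved)."""
    labels = np.asarray(labels)
    out = np.where(labels == ACTIVE_CARRY_CODE, 1, 0)
    return np.where(labels < 0, -1, out)


def train_acd(frames_list: list, carrying_list: list, subjects: list[str],
              clf_params: dict | None = None, seed: int = 0) -> dict:
    """Train the binary active-carrying detector with leave-one-subject-out
    evaluation. Returns per-recording held-out predictions, the compounded
    confusion, accuracy and per-class recall/precision, plus a final
    detector trained on all data."""
    binary = [collapse_carrying(c) for c in carrying_list]
    params = dict(n_classes=2, seed=seed)
    params.update(clf_params or {})

    uniq = sorted(set(subjects))
    preds: list = [None] * len(frames_list)
    pairs = []
    for si, subj in enumerate(uniq):
        test_idx = [i for i, s in enumerate(subjects) if s == subj]
        train_idx = [i for i, s in enumerate(subjects) if s != subj]
        clf = MotorClassifier(**{**params, "seed": seed + si})
        clf.fit([frames_list[i] for i in train_idx],
                [binary[i] for i in train_idx])
        for i in test_idx:
            p = clf.predict(frames_list[i])
            preds[i] = p
            pairs.append((binary[i], p))
    cm = compound_confusion(pairs, ACD_CLASSES)
    metrics = per_class_metrics(cm)

    final = MotorClassifier(**params)
    final.fit(frames_list, binary)
    return dict(predictions=preds, confusion=cm, metrics=metrics,
                accuracy=metrics["accuracy"], model=final, n_folds=len(uniq))


def acd_filter(predictions: np.ndarray) -> tuple[np.ndarray, float]:
    """Mask of frames retained for downstream analysis (active-carry frames
    excluded) and the retained fraction."""
    predictions = np.asarray(predictions)
    mask = predictions != 1
    retained = float(mask.mean()) if len(mask) else 0.0
    if not mask.any():
        import warnings
        warnings.warn("all frames predicted as carrying; downstream input empty")
    return mask, retained
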