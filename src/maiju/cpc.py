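"""Contrastive predictive coding (CPC) on unannotated recordings.

The frame encoder (same architecture as the supervised classifier's
encoder) maps each 2.3-s frame to a latent vector Z_t; a gated recurrent
unit summarizes the latent history into a context vector C_t; a linear
projection of C_t predicts the latent k frames ahead. Training minimizes
the InfoNCE loss: the cross-entropy of identifying the true future latent
Z_{t+k} among negative latents drawn from the same recording, under a
dot-product similarity. The chance baseline of the loss with N negatives
is ln(1 + N); any learnable temporal structure pushes the loss below it.

With 120-sample frames hopped by 60 samples at 52 Hz, the default
prediction distance k = 5 frames looks 5 * 60/52 ~ 5.8 s into the future.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import nn
from .taxonomy import FRAME_HOP, FRAME_LEN, SAMPLE_RATE


@dataclass
class CPCConfig:
    latent_dim: int = 128
    k: int = 5                  # prediction distance in frames
    n_negatives: int = 10
    epochs: int = 50
    lr: float = 1e-3
    window: int = 64            # frames per training window
    batch_windows: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("prediction distance k must be >= 1")
        if self.n_negatives < 1:
            raise ValueError("n_negatives must be >= 1")


def lookahead_seconds(k: int = 5, hop: int = FRAME_HOP,
                      rate: float = SAMPLE_RATE) -> float:
    """Time the k-frame prediction distance spans, in seconds."""
    return k * hop / rate


def infonce_loss(pred: np.ndarray, positive: np.ndarray,
                 negatives: np.ndarray) -> float:
    """InfoNCE loss under dot-product similarity.

    pred, positive: [M, n]; negatives: [M, N, n]. Returns the mean
    cross-entropy of picking the positive among the N+1 candidates;
    equals ln(1 + N) when all similarities are equal.
    """
    pred = np.asarray(pred, float)
    positive = np.asarray(positive, float)
    negatives = np.asarray(negatives, float)
    s_pos = (pred * positive).sum(axis=1, keepdims=True)
    s_neg = np.einsum("mn,mkn->mk", pred, negatives)
    scores = np.concatenate([s_pos, s_neg], axis=1)
    z = scores - scores.max(axis=1, keepdims=True)
    logp = z[:, 0] - np.log(np.exp(z).sum(axis=1))
    return float(-logp.mean())


@dataclass
class LatentSequence:
    """Per-frame encoder latents Z, context vectors C, and the linear
    prediction of the latent k frames ahead (defined for t <= T - k)."""

    Z: np.ndarray
    C: np.ndarray
    Z_pred: np.ndarray
    k: int


class CPCPretrainer(BaseEstimator, TransformerMixin):
    """Self-supervised encoder pretraining with CPC.

    fit(X) takes a list of per-recording frame arrays [F_i, 120, 24];
    transform(frames) returns the LatentSequence of one recording.

    Attributes (after fit)
    ----------------------
    history_ : per-epoch mean InfoNCE loss
    baseline_ : chance-level loss ln(1 + n_negatives)
    """

    def __init__(self, latent_dim: int = 128, k: int = 5, n_negatives: int = 10,
                 epochs: int = 50, lr: float = 1e-3, window: int = 64,
                 batch_windows: int = 4, encoder_widths: tuple = (32, 64),
                 seed: int = 0):
        self.latent_dim = latent_dim
        self.k = k
        self.n_negatives = n_negatives
        self.epochs = epochs
        self.lr = lr
        self.window = window
        self.batch_windows = batch_windows
        self.encoder_widths = encoder_widths
        self.seed = seed

    def _build(self, rng: np.random.Generator) -> None:
        self.encoder_ = nn.FrameEncoder(rng, latent_dim=self.latent_dim,
                                        widths=self.encoder_widths)
        self.gru_ = nn.GRU(rng, self.latent_dim, self.latent_dim)
        self.proj_ = nn.Dense(rng, self.latent_dim, self.latent_dim, scale=0.1)
        self._params = (self.encoder_.parameters() + self.gru_.parameters()
                        + self.proj_.parameters())

    def _loss_on_windows(self, windows: np.ndarray,
                         rng: np.random.Generator) -> nn.Tensor:
        """InfoNCE loss over a batch of frame windows [B, W, 120, 24]."""
        from .classifier import INPUT_SCALE

        b, w = windows.shape[:2]
        k, nneg = self.k, self.n_negatives
        flat = windows.reshape(b * w, FRAME_LEN, 24) * INPUT_SCALE
        z = self.encoder_(nn.Tensor(flat))               # [B*W, n]
        z_seq = z.reshape(b, w, self.latent_dim)
        c = self.gru_(z_seq)                             # [B, W, n]
        m = w - k                                        # predictions per window
        preds = self.proj_(
            _slice_time(c, 0, m).reshape(b * m, self.latent_dim))

        # positive index of prediction (bi, t) in the flat [B*W] latent array
        bi = np.repeat(np.arange(b), m)
        ti = np.tile(np.arange(m), b)
        pos_idx = bi * w + ti + k
        # negatives: frames from the same window batch, never the positive
        neg = rng.integers(0, b * w - 1, size=(b * m, nneg))
        neg = neg + (neg >= pos_idx[:, None])

        pos = z.take(pos_idx)                            # [B*m, n]
        negs = z.take(neg.reshape(-1)).reshape(b * m, nneg, self.latent_dim)

        s_pos = (preds * pos).sum(axis=1, keepdims=True)
        s_neg = (preds.reshape(b * m, 1, self.latent_dim) * negs).sum(axis=2)
        scores = nn.concat([s_pos, s_neg], axis=1)
        targets = np.zeros((b * m, nneg + 1))
        targets[:, 0] = 1.0
        return nn.softmax_cross_entropy(scores, targets)

    def fit(self, X: list, y=None):
        X = [np.asarray(xi, float) for xi in X]
        if not X:
            raise ValueError("no recordings given")
        for xi in X:
            if xi.shape[0] < self.k + 12:
                raise ValueError(
                    f"recording with {xi.shape[0]} frames is too short "
                    f"(need >= k + 12 = {self.k + 12})")
        rng = np.random.default_rng(self.seed)
        self._build(rng)
        self.baseline_ = float(np.log(1 + self.n_negatives))
        opt = nn.Adam(self._params, lr=self.lr)

        total = sum(xi.shape[0] for xi in X)
        steps = max(1, total // (self.window * self.batch_windows))
        rec_p = np.array([xi.shape[0] for xi in X], float)
        rec_p /= rec_p.sum()

        self.history_ = []
        for _ in range(self.epochs):
            losses = []
            for _ in range(steps):
                # all windows of a batch come from one recording, so the
                # negatives are drawn from the same recording as the positive
                r = int(rng.choice(len(X), p=rec_p))
                f = X[r].shape[0]
                w = min(self.window, f)
                batch = []
                for _ in range(self.batch_windows):
                    start = int(rng.integers(0, f - w + 1))
                    win = X[r][start:start + w]
                    if w < self.window:  # pad by repetition for stacking
                        reps = int(np.ceil(self.window / w))
                        win = np.concatenate([win] * reps)[:self.window]
                    batch.append(win)
                loss = self._loss_on_windows(np.stack(batch), rng)
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"non-finite InfoNCE loss: {loss.data}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            self.history_.append(float(np.mean(losses)))
        return self

    def mean_loss(self, X: list, seed: int = 0) -> float:
        """Mean InfoNCE loss over recordings without updating parameters.

        Windows are batched per recording exactly as in training, so the
        negatives come from the same recording as the positives.
        """
        rng = np.random.default_rng(seed)
        losses = []
        for xi in X:
            xi = np.asarray(xi, float)
            w = min(self.window, xi.shape[0])
            wins = [xi[s:s + w] for s in range(0, xi.shape[0] - w + 1, w)]
            for i in range(0, len(wins), self.batch_windows):
                batch = np.stack(wins[i:i + self.batch_windows])
                loss = self._loss_on_windows(batch, rng)
                losses.append(float(loss.data))
        return float(np.mean(losses))

    def transform(self, frames: np.ndarray) -> LatentSequence:
        """Extract per-frame latents Z, contexts C and future predictions."""
        from .classifier import INPUT_SCALE

        frames = np.asarray(frames, float) * INPUT_SCALE
        zs = []
        for i in range(0, frames.shape[0], 256):
            zs.append(self.encoder_(nn.Tensor(frames[i:i + 256])).data)
        z = np.concatenate(zs)
        c = self.gru_(nn.Tensor(z[None, :, :])).data[0]
        z_pred = c[:max(len(z) - self.k, 0)] @ self.proj_.w.data + self.proj_.b.data
        return LatentSequence(Z=z, C=c, Z_pred=z_pred, k=self.k)


def _slice_time(x: nn.Tensor, start: int, length: int) -> nn.Tensor:
    """Select x[:, start:start+length, :] from a [B, T, C] tensor."""
    out = nn.Tensor(x.data[:, start:start + length, :], (x,))

    def bw(g):
        acc = np.zeros_like(x.data)
        acc[:, start:start + length, :] = g
        x._accum(acc)
    out._backward = bw
    return out
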