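"""Network building blocks: dense, 1-D convolution, GRU, and the encoder /
temporal-classifier modules used by the motor-ability networks."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv1d, leaky_relu, sigmoid, stack, tanh


class Module:
    def parameters(self) -> list[Tensor]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Tensor):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor):
                        out.append(item)
        return out

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data[...] = s


def _he(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    return Tensor(rng.standard_normal(shape) * np.sqrt(2.0 / fan_in))


class Dense(Module):
    def __init__(self, rng, n_in: int, n_out: int, scale: float = 1.0):
        self.w = Tensor(rng.standard_normal((n_in, n_out))
                        * scale * np.sqrt(2.0 / n_in))
        self.b = Tensor(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    def __init__(self, rng, cin: int, cout: int, fw: int, stride: int = 1,
                 pad: int = 0, dilation: int = 1):
        self.w = _he(rng, (fw, cin, cout), fw * cin)
        self.b = Tensor(np.zeros(cout))
        self.stride, self.pad, self.dilation = stride, pad, dilation

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, stride=self.stride, pad=self.pad,
                      dilation=self.dilation)


class GRU(Module):
    """Gated recurrent unit over [B, T, n_in] -> [B, T, n_hidden]."""

    def __init__(self, rng, n_in: int, n_hidden: int):
        s = 1.0 / np.sqrt(n_in)
        sh = 1.0 / np.sqrt(n_hidden)
        self.wz = Tensor(rng.uniform(-s, s, (n_in, n_hidden)))
        self.uz = Tensor(rng.uniform(-sh, sh, (n_hidden, n_hidden)))
        self.bz = Tensor(np.zeros(n_hidden))
        self.wr = Tensor(rng.uniform(-s, s, (n_in, n_hidden)))
        self.ur = Tensor(rng.uniform(-sh, sh, (n_hidden, n_hidden)))
        self.br = Tensor(np.zeros(n_hidden))
        self.wh = Tensor(rng.uniform(-s, s, (n_in, n_hidden)))
        self.uh = Tensor(rng.uniform(-sh, sh, (n_hidden, n_hidden)))
        self.bh = Tensor(np.zeros(n_hidden))
        self.n_hidden = n_hidden

    def __call__(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        h = Tensor(np.zeros((b, self.n_hidden)))
        outs = []
        for i in range(t):
            xt = _time_slice(x, i)
            z = sigmoid(xt @ self.wz + h @ self.uz + self.bz)
            r = sigmoid(xt @ self.wr + h @ self.ur + self.br)
            hh = tanh(xt @ self.wh + (r * h) @ self.uh + self.bh)
            h = (1.0 - z) * h + z * hh
            outs.append(h)
        return stack(outs, axis=1)


def _time_slice(x: Tensor, i: int) -> Tensor:
    """Select x[:, i, :] from a [B, T, C] tensor."""
    out = Tensor(x.data[:, i, :], (x,))

    def bw(g):
        acc = np.zeros_like(x.data)
        acc[:, i, :] = g
        x._accum(acc)
    out._backward = bw
    return out


class FrameEncoder(Module):
    """Frame-level sensor-fusion encoder: [N, 120, 24] -> [N, latent_dim].

    Three strided convolution blocks with leaky-ReLU activations followed
    by temporal average pooling.
    """

    def __init__(self, rng, latent_dim: int = 160, widths=(32, 64)):
        w1, w2 = widths
        self.c1 = Conv1d(rng, 24, w1, fw=7, stride=3, pad=2)
        self.c2 = Conv1d(rng, w1, w2, fw=5, stride=2, pad=2)
        self.c3 = Conv1d(rng, w2, latent_dim, fw=5, stride=2, pad=2)
        self.latent_dim = latent_dim

    def __call__(self, x: Tensor) -> Tensor:
        h = leaky_relu(self.c1(x))
        h = leaky_relu(self.c2(h))
        h = leaky_relu(self.c3(h))
        return h.mean(axis=1)


class TemporalClassifier(Module):
    """Dilated temporal convolution stack over the frame-latent sequence:
    [1, T, latent] -> per-frame class logits [T, K]."""

    def __init__(self, rng, latent_dim: int, n_classes: int, width: int = 64,
                 dilations=(1, 2, 4, 8)):
        self.blocks = []
        cin = latent_dim
        for d in dilations:
            self.blocks.append(Conv1d(rng, cin, width, fw=3, pad=d, dilation=d))
            cin = width
        self.head = Dense(rng, cin, n_classes)

    def __call__(self, z: Tensor) -> Tensor:
        h = z
        for blk in self.blocks:
            h = leaky_relu(blk(h))
        t = h.shape[1]
        return self.head(h.reshape(t, -1))
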