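"""Minimal fully convolutional network primitives with explicit backprop.

The labeling model and its synthesis replica are small dilated-residual
convolutional stacks; everything here is plain numpy (float32, im2col
convolutions backed by BLAS matmuls).  Layers cache their forward activations
and expose ``backward`` returning the gradient with respect to their input
while accumulating parameter gradients, which makes the asymmetric gradient
routing of the dual-pathway trainer straightforward to express.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit


class Conv2d:
    """2-D convolution, stride 1, 'same' zero padding, optional dilation.

    Input/output layout is (channels, H, W); weights are He-initialised.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 dilation: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.d = in_ch, out_ch, kernel, dilation
        fan_in = in_ch * kernel * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_ch, fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int] | None = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def params_and_grads(self):
        yield self.W, self.dW
        yield self.b, self.db

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        p = self.d * (self.k // 2)
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        span = self.d * (self.k - 1) + 1
        win = sliding_window_view(xp, (span, span), axis=(1, 2))[:, :, :, ::self.d, ::self.d]
        # (C, H, W, k, k) -> (H*W, C*k*k)
        return np.ascontiguousarray(win.transpose(1, 2, 0, 3, 4)).reshape(h * w, -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        cols = self._im2col(x.astype(np.float32, copy=False))
        self._cols, self._shape = cols, (h, w)
        y = cols @ self.W.T + self.b
        return y.T.reshape(self.out_ch, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h, w = self._shape
        dy = dout.reshape(self.out_ch, h * w).T.astype(np.float32, copy=False)
        self.dW += dy.T @ self._cols
        self.db += dy.sum(axis=0)
        dcols = dy @ self.W                       # (H*W, C*k*k)
        dcols = dcols.reshape(h, w, self.in_ch, self.k, self.k)
        p = self.d * (self.k // 2)
        dxp = np.zeros((self.in_ch, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, ki * self.d:ki * self.d + h, kj * self.d:kj * self.d + w] += \
                    dcols[:, :, :, ki, kj].transpose(2, 0, 1)
        return dxp[:, p:p + h, p:p + w] if p else dxp

    def zero_grad(self) -> None:
        self.dW[...] = 0.0
        self.db[...] = 0.0


class FCN:
    """Dilated-residual fully convolutional stack.

    stem conv -> ReLU -> residual blocks (x = x + ReLU(conv_dilated(x)))
    -> 1x1 head.  The head output is raw; activation (softmax / sigmoid) is
    applied by the caller so its backward can be fused with the loss.
    """

    def __init__(self, in_ch: int, out_ch: int, base_channels: int = 32,
                 dilations: tuple[int, ...] = (1, 2, 4, 8),
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.stem = Conv2d(in_ch, base_channels, 3, 1, rng)
        self.blocks = [Conv2d(base_channels, base_channels, 3, d, rng)
                       for d in dilations]
        self.head = Conv2d(base_channels, out_ch, 1, 1, rng)
        self._cache: dict = {}

    @property
    def layers(self) -> list[Conv2d]:
        return [self.stem, *self.blocks, self.head]

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.stem.forward(x)
        h = np.maximum(s, 0.0)
        pre, acts = [], []
        for conv in self.blocks:
            y = conv.forward(h)
            pre.append(y)
            acts.append(h)
            h = h + np.maximum(y, 0.0)
        self._cache = {"stem_pre": s, "block_pre": pre, "block_in": acts}
        return self.head.forward(h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.head.backward(dout)
        for conv, y in zip(reversed(self.blocks), reversed(self._cache["block_pre"])):
            dy = dh * (y > 0)
            dh = dh + conv.backward(dy)
        ds = dh * (self._cache["stem_pre"] > 0)
        return self.stem.backward(ds)

    def zero_grad(self) -> None:
        for l in self.layers:
            l.zero_grad()

    def state(self) -> list[np.ndarray]:
        out = []
        for l in self.layers:
            out.extend([l.W.copy(), l.b.copy()])
        return out

    def load_state(self, state: list[np.ndarray]) -> None:
        i = 0
        for l in self.layers:
            l.W[...] = state[i]
            l.b[...] = state[i + 1]
            i += 2


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    dot = (dprobs * probs).sum(axis=0, keepdims=True)
    return probs * (dprobs - dot)


def sigmoid(logits: np.ndarray) -> np.ndarray:
    return expit(logits)


def sigmoid_backward(out: np.ndarray, dout: np.ndarray) -> np.ndarray:
    return dout * out * (1.0 - out)


class Adam:
    def __init__(self, nets, lr: float = 3e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = [pg for net in nets for l in net.layers
                      for pg in l.params_and_grads()]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
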