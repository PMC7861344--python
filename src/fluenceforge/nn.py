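"""Minimal CNN machinery: strided 2-D convolutions, transposed convolutions,
Swish/ReLU/Softplus activations, Adam, and a generic early-stopping training
loop.  Everything is float32 numpy with hand-written backpropagation;
layer gradients are verified against finite differences in the test suite.

Data layout is channels-last: ``(N, H, W, C)``; convolutions are computed
as one GEMM per kernel tap over strided views, which keeps memory traffic
low on a single core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

DTYPE = np.float32


# ---------------------------------------------------------------------------
# Activations
# ---------------------------------------------------------------------------

def swish(x: np.ndarray | float) -> np.ndarray | float:
    """Swish(x) = x * sigmoid(x) = x / (exp(-x) + 1)."""
    x = np.asarray(x)
    out = x / (np.exp(-x) + 1.0)
    return out if out.ndim else float(out)


def _sigmoid(x):
    return expit(x)


class Swish:
    def forward(self, x, train=True):
        if train:
            self._x = x
        return x * _sigmoid(x)

    def backward(self, g):
        s = _sigmoid(self._x)
        return g * (s + self._x * s * (1.0 - s))

    def params(self):
        return []


class ReLU:
    def forward(self, x, train=True):
        if train:
            self._m = x > 0
        return np.maximum(x, 0.0)

    def backward(self, g):
        return g * self._m

    def params(self):
        return []


class Softplus:
    """log(1 + exp(x)); smooth nonnegativity for the network output."""

    def forward(self, x, train=True):
        if train:
            self._x = x
        return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)

    def backward(self, g):
        return g * _sigmoid(self._x)

    def params(self):
        return []


def make_activation(name: str):
    return {"swish": Swish, "relu": ReLU, "softplus": Softplus}[name]()


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Conv2D:
    """2-D convolution (cross-correlation), channels-last.

    'Same' output for stride 1 with odd k; exact halving for stride 2 with
    k=4, p=1 on even sizes.  Weights are (k, k, c_in, c_out); the forward
    pass is one GEMM per kernel tap over a strided view of the padded input.
    """

    def __init__(self, c_in, c_out, k=3, stride=1, rng=None, pad=None):
        self.k, self.s = k, stride
        self.p = (k - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (c_in * k * k))
        self.W = Param(rng.normal(0.0, std, size=(k, k, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.c_in, self.c_out = c_in, c_out

    def _tap(self, xp, ki, kj, ho, wo):
        return xp[:, ki : ki + self.s * ho : self.s, kj : kj + self.s * wo : self.s, :]

    def forward(self, x, train=True):
        x = x.astype(DTYPE, copy=False)
        n, h, w, _ = x.shape
        p, k, s = self.p, self.k, self.s
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        out = np.broadcast_to(self.b.value, (n, ho, wo, self.c_out)).copy()
        for ki in range(k):
            for kj in range(k):
                out += np.tensordot(
                    self._tap(xp, ki, kj, ho, wo), self.W.value[ki, kj], ([3], [0])
                )
        if train:
            self._xp, self._hw, self._howo = xp, (h, w), (ho, wo)
        return out

    def backward(self, g):
        g = g.astype(DTYPE, copy=False)
        h, w = self._hw
        ho, wo = self._howo
        xp = self._xp
        dxp = np.zeros_like(xp)
        for ki in range(self.k):
            for kj in range(self.k):
                xs = self._tap(xp, ki, kj, ho, wo)
                self.W.grad[ki, kj] = np.tensordot(xs, g, ([0, 1, 2], [0, 1, 2]))
                self._tap(dxp, ki, kj, ho, wo)[...] += np.tensordot(
                    g, self.W.value[ki, kj], ([3], [1])
                )
        self.b.grad[...] = g.sum(axis=(0, 1, 2))
        p = self.p
        return dxp[:, p : p + h, p : p + w, :] if p else dxp

    def params(self):
        return [self.W, self.b]


class ConvTranspose2D:
    """Stride-2 transposed convolution (k=4, p=1), channels-last: exact
    doubling of H and W.  The forward pass is the adjoint scatter of Conv2D."""

    def __init__(self, c_in, c_out, k=4, stride=2, rng=None, pad=1):
        self.k, self.s, self.p = k, stride, pad
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (c_in * k * k))
        self.W = Param(rng.normal(0.0, std, size=(k, k, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.c_in, self.c_out = c_in, c_out

    def _out_size(self, h):
        return (h - 1) * self.s - 2 * self.p + self.k

    def forward(self, x, train=True):
        x = x.astype(DTYPE, copy=False)
        n, h, w, _ = x.shape
        k, s, p = self.k, self.s, self.p
        ho, wo = self._out_size(h), self._out_size(w)
        yp = np.zeros((n, ho + 2 * p, wo + 2 * p, self.c_out), dtype=DTYPE)
        for ki in range(k):
            for kj in range(k):
                yp[:, ki : ki + s * h : s, kj : kj + s * w : s, :] += np.tensordot(
                    x, self.W.value[ki, kj], ([3], [0])
                )
        out = yp[:, p : p + ho, p : p + wo, :] + self.b.value
        if train:
            self._x, self._hw = x, (h, w)
        return out

    def backward(self, g):
        g = g.astype(DTYPE, copy=False)
        h, w = self._hw
        k, s, p = self.k, self.s, self.p
        gp = np.pad(g, ((0, 0), (p, p), (p, p), (0, 0))) if p else g
        dx = np.zeros_like(self._x)
        for ki in range(k):
            for kj in range(k):
                gs = gp[:, ki : ki + s * h : s, kj : kj + s * w : s, :]
                self.W.grad[ki, kj] = np.tensordot(self._x, gs, ([0, 1, 2], [0, 1, 2]))
                dx += np.tensordot(gs, self.W.value[ki, kj], ([3], [1]))
        self.b.grad[...] = g.sum(axis=(0, 1, 2))
        return dx

    def params(self):
        return [self.W, self.b]


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: Sequence[Param], lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p in self.params:
            p.m = self.b1 * p.m + (1.0 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Checkpointing helpers
# ---------------------------------------------------------------------------

def get_weights(model) -> list[np.ndarray]:
    return [p.value.copy() for p in model.params()]


def set_weights(model, weights: Sequence[np.ndarray]) -> None:
    for p, w in zip(model.params(), weights, strict=True):
        p.value[...] = w


def n_params(model) -> int:
    return int(sum(p.value.size for p in model.params()))


# ---------------------------------------------------------------------------
# Training loop with validation holdout and early stopping
# ---------------------------------------------------------------------------

@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False


def train_network(
    model,
    inputs: Sequence[np.ndarray],
    targets: Sequence[np.ndarray],
    loss_fn: Callable,
    lr: float = 1e-3,
    patience: int = 8,
    val_fraction: float = 0.10,
    batch_size: int = 16,
    max_epochs: int = 200,
    seed: int = 0,
) -> TrainHistory:
    """Adam training with a random validation holdout and early stopping.

    ``loss_fn(pred, *target_batch)`` must return ``(value, grad_wrt_pred)``.
    Samples are shuffled with the seed before the holdout is taken; training
    stops when validation loss has not improved for ``patience`` epochs and
    the best-validation weights are restored.  NaN loss aborts.
    """
    n = inputs[0].shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to train")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        tr_idx, val_idx = val_idx, val_idx

    def run_batches(idx, train):
        total, count = 0.0, 0
        for start in range(0, idx.size, batch_size):
            sel = idx[start : start + batch_size]
            xb = [a[sel] for a in inputs]
            tb = [a[sel] for a in targets]
            pred = model.forward(*xb, train=train)
            val, grad = loss_fn(pred, *tb)
            if not np.isfinite(val):
                raise RuntimeError(f"non-finite loss ({val}) during training")
            if train:
                model.backward(grad.astype(DTYPE))
                opt.step()
            total += float(val) * sel.size
            count += sel.size
        return total / count

    opt = Adam(model.params(), lr=lr)
    history = TrainHistory()
    best_val = np.inf
    best_weights = get_weights(model)
    since_best = 0
    for epoch in range(max_epochs):
        order = tr_idx[rng.permutation(tr_idx.size)]
        tr_loss = run_batches(order, train=True)
        val_loss = run_batches(val_idx, train=False)
        history.train_loss.append(tr_loss)
        history.val_loss.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = get_weights(model)
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                history.stopped_early = True
                break
    set_weights(model, best_weights)
    return history
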