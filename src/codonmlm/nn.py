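"""Minimal neural-network kernel: NumPy layers with explicit forward and
backward passes, plus an Adam optimizer.

Every layer caches what its backward pass needs during ``forward`` and is
used exactly once per forward pass (the encoder instantiates one layer
object per occurrence).  float64 throughout: the models here are small and
exact gradient checks matter more than raw speed.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy.special import erf

NEG_INF = -1e30


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, name: str = "") -> None:
        self.W = Param(_glorot(rng, d_in, d_out), f"{name}.W")
        self.b = Param(np.zeros(d_out), f"{name}.b")
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += np.tensordot(x, dy, axes=(tuple(range(x.ndim - 1)),) * 2)
        self.b.grad += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        return dy @ self.W.value.T

    def params(self) -> list[Param]:
        return [self.W, self.b]


class LayerNorm:
    def __init__(self, dim: int, name: str = "", eps: float = 1e-6) -> None:
        self.gamma = Param(np.ones(dim), f"{name}.gamma")
        self.beta = Param(np.zeros(dim), f"{name}.beta")
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        d = xhat.shape[-1]
        self.gamma.grad += (dy * xhat).reshape(-1, d).sum(axis=0)
        self.beta.grad += dy.reshape(-1, d).sum(axis=0)
        dxhat = dy * self.gamma.value
        # standard layer-norm backward over the last axis
        return inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class Gelu:
    """Exact GELU via the Gaussian CDF."""

    def __init__(self) -> None:
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x * 0.5 * (1.0 + erf(x / math.sqrt(2.0)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        return dy * (cdf + x * pdf)

    def params(self) -> list[Param]:
        return []


class Dropout:
    """Inverted dropout; identity when rate is 0 or in eval mode."""

    def __init__(self, rate: float) -> None:
        self.rate = rate
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool, rng: Optional[np.random.Generator]) -> np.ndarray:
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask

    def params(self) -> list[Param]:
        return []


class Embedding:
    def __init__(self, vocab: int, dim: int, rng: np.random.Generator, name: str = "") -> None:
        self.table = Param(rng.normal(0.0, 0.02, size=(vocab, dim)), f"{name}.table")
        self._ids: Optional[np.ndarray] = None

    def forward(self, ids: np.ndarray) -> np.ndarray:
        self._ids = ids
        return self.table.value[ids]

    def backward(self, dy: np.ndarray) -> None:
        np.add.at(self.table.grad, self._ids, dy)

    def params(self) -> list[Param]:
        return [self.table]


class MultiHeadAttention:
    """Scaled dot-product attention with a key-padding mask.

    ``forward(q_in, kv_in, key_mask)`` where key_mask is boolean (B, Lk)
    with True at real (attendable) positions.  ``backward`` returns the
    gradients with respect to q_in and kv_in separately; a self-attention
    caller sums them.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator, name: str = "") -> None:
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.h = n_heads
        self.dk = d_model // n_heads
        self.wq = Dense(d_model, d_model, rng, f"{name}.wq")
        self.wk = Dense(d_model, d_model, rng, f"{name}.wk")
        self.wv = Dense(d_model, d_model, rng, f"{name}.wv")
        self.wo = Dense(d_model, d_model, rng, f"{name}.wo")
        self._cache = None

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, l, d = x.shape
        return x.reshape(b, l, self.h, self.dk).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, h, l, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, l, h * dk)

    def forward(self, q_in: np.ndarray, kv_in: np.ndarray, key_mask: np.ndarray) -> np.ndarray:
        q = self._split(self.wq.forward(q_in))
        k = self._split(self.wk.forward(kv_in))
        v = self._split(self.wv.forward(kv_in))
        scores = q @ k.transpose(0, 1, 3, 2) / math.sqrt(self.dk)
        scores = np.where(key_mask[:, None, None, :], scores, NEG_INF)
        scores -= scores.max(axis=-1, keepdims=True)
        ex = np.exp(scores)
        attn = ex / ex.sum(axis=-1, keepdims=True)
        ctx = attn @ v
        out = self.wo.forward(self._merge(ctx))
        self._cache = (q, k, v, attn, key_mask)
        return out

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        q, k, v, attn, key_mask = self._cache
        dctx = self._split(self.wo.backward(dout))
        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx
        # softmax backward
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores = np.where(key_mask[:, None, None, :], dscores, 0.0)
        dscores /= math.sqrt(self.dk)
        dq = dscores @ k
        dk_ = dscores.transpose(0, 1, 3, 2) @ q
        dq_in = self.wq.backward(self._merge(dq))
        dkv_in = self.wk.backward(self._merge(dk_)) + self.wv.backward(self._merge(dv))
        return dq_in, dkv_in

    def params(self) -> list[Param]:
        return self.wq.params() + self.wk.params() + self.wv.params() + self.wo.params()


class FeedForward:
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator, name: str = "") -> None:
        self.fc1 = Dense(d_model, d_ff, rng, f"{name}.fc1")
        self.act = Gelu()
        self.fc2 = Dense(d_ff, d_model, rng, f"{name}.fc2")

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.fc2.forward(self.act.forward(self.fc1.forward(x)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.fc1.backward(self.act.backward(self.fc2.backward(dy)))

    def params(self) -> list[Param]:
        return self.fc1.params() + self.fc2.params()


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, ignore_index: int = -100
) -> tuple[float, int, np.ndarray]:
    """Mean cross-entropy over positions with labels != ignore_index.

    Returns (mean_loss, n_labeled, dlogits) where dlogits is the gradient
    of the *mean* loss.
    """
    mask = labels != ignore_index
    n = int(mask.sum())
    dlogits = np.zeros_like(logits)
    if n == 0:
        return 0.0, 0, dlogits
    z = logits[mask]
    z = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=-1, keepdims=True)
    idx = np.arange(n)
    tgt = labels[mask]
    loss = -np.mean(np.log(probs[idx, tgt] + 1e-300))
    grad = probs
    grad[idx, tgt] -= 1.0
    dlogits[mask] = grad / n
    return float(loss), n, dlogits


class Adam:
    """Adam with bias correction; state keyed by parameter identity order."""

    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = state["t"]
        self.m = [m.copy() for m in state["m"]]
        self.v = [v.copy() for v in state["v"]]
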