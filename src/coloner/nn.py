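"""Minimal neural-network layers with manual backpropagation (numpy).

Implements exactly what the sequence tagger needs: an embedding lookup, a
(bi)directional LSTM with backpropagation through time, a dense projection,
token-level softmax losses (categorical cross-entropy, KL divergence,
Poisson) for the no-CRF variants, and the RMSProp/Adam/Nadam optimizers.
Everything is float64 and deterministic given the seeded initializer, so
training runs are bit-reproducible on one machine.

Sequences are padded at the tail; because the recurrences are causal (the
right-to-left pass runs over length-reversed valid prefixes), padded
positions never influence valid ones, and their loss gradients are masked
to zero.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def reverse_padded(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse the first ``lengths[b]`` entries of each row; padding stays put."""
    B, T = x.shape[:2]
    ar = np.arange(T)[None, :]
    idx = np.where(ar < lengths[:, None], lengths[:, None] - 1 - ar, ar)
    return x[np.arange(B)[:, None], idx]


class Embedding:
    """Token-id -> vector lookup; the PAD row (index 0) is pinned to zero."""

    def __init__(self, weights: np.ndarray, trainable: bool = True):
        self.W = np.array(weights, dtype=np.float64)
        self.W[0] = 0.0
        self.trainable = trainable
        self.dW = np.zeros_like(self.W)
        self._ids = None

    def forward(self, ids: np.ndarray) -> np.ndarray:
        self._ids = ids
        return self.W[ids]

    def backward(self, d_out: np.ndarray) -> None:
        if not self.trainable:
            return
        np.add.at(self.dW, self._ids, d_out)
        self.dW[0] = 0.0

    def params(self, prefix=""):
        if self.trainable:
            yield prefix + "W", self.W, self.dW

    def zero_grad(self):
        self.dW[:] = 0.0


class LSTM:
    """Single-direction LSTM over padded batches, with full BPTT.

    Gate layout in the fused weight matrices is ``[i, f, g, o]``.  The
    forget-gate bias is initialized to 1.
    """

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        H = hidden_dim
        self.H = H
        self.Wx = glorot(rng, input_dim, 4 * H)
        self.Wh = glorot(rng, H, 4 * H, shape=(H, 4 * H))
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, D = x.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.zeros((B, T, H))
        cache = []
        xw = x.reshape(B * T, D) @ self.Wx
        xw = xw.reshape(B, T, 4 * H)
        for t in range(T):
            z = xw[:, t] + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, t] = h
        self._cache = (x, cache)
        return hs

    def backward(self, d_hs: np.ndarray) -> np.ndarray:
        x, cache = self._cache
        B, T, D = x.shape
        H = self.H
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        dz_all = np.zeros((B, T, 4 * H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = d_hs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dz_all[:, t] = dz
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
            self.dWh += h_prev.T @ dz
        dz_flat = dz_all.reshape(B * T, 4 * H)
        self.dWx += x.reshape(B * T, D).T @ dz_flat
        self.db += dz_flat.sum(axis=0)
        dx = dz_flat @ self.Wx.T
        return dx.reshape(B, T, D)

    def params(self, prefix=""):
        yield prefix + "Wx", self.Wx, self.dWx
        yield prefix + "Wh", self.Wh, self.dWh
        yield prefix + "b", self.b, self.db

    def zero_grad(self):
        self.dWx[:] = 0.0
        self.dWh[:] = 0.0
        self.db[:] = 0.0


class BiLSTM:
    """Forward and length-reversed backward LSTM, outputs concatenated."""

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.fwd = LSTM(input_dim, hidden_dim, rng)
        self.bwd = LSTM(input_dim, hidden_dim, rng)
        self._lengths = None

    def forward(self, x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        self._lengths = lengths
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(reverse_padded(x, lengths))
        hb = reverse_padded(hb, lengths)
        return np.concatenate([hf, hb], axis=2)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        H = self.fwd.H
        dx = self.fwd.backward(d_out[:, :, :H])
        dhb = reverse_padded(d_out[:, :, H:], self._lengths)
        dx += reverse_padded(self.bwd.backward(dhb), self._lengths)
        return dx

    def params(self, prefix=""):
        yield from self.fwd.params(prefix + "fwd_")
        yield from self.bwd.params(prefix + "bwd_")

    def zero_grad(self):
        self.fwd.zero_grad()
        self.bwd.zero_grad()


class Dense:
    """Affine projection applied per token."""

    def __init__(self, input_dim: int, output_dim: int, rng: np.random.Generator):
        self.W = glorot(rng, input_dim, output_dim)
        self.b = np.zeros(output_dim)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        B, T, D = self._x.shape
        x2 = self._x.reshape(B * T, D)
        d2 = d_out.reshape(B * T, -1)
        self.dW += x2.T @ d2
        self.db += d2.sum(axis=0)
        return (d2 @ self.W.T).reshape(B, T, D)

    def params(self, prefix=""):
        yield prefix + "W", self.W, self.dW
        yield prefix + "b", self.b, self.db

    def zero_grad(self):
        self.dW[:] = 0.0
        self.db[:] = 0.0


# ---------------------------------------------------------------------------
# Token-level softmax losses (no-CRF variants)
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def token_loss(logits: np.ndarray, targets: np.ndarray, mask: np.ndarray,
               kind: str = "cce") -> tuple[float, np.ndarray]:
    """Masked token-level loss and its gradient w.r.t. the logits.

    ``cce``: categorical cross-entropy.  ``kl``: KL divergence from the
    one-hot target, which equals cross-entropy up to the (zero) target
    entropy, so it shares the gradient.  ``poisson``: the elementwise
    Poisson deviance ``mean_k(p_k - y_k log p_k)`` on the softmax output.
    Loss is averaged over unmasked tokens.
    """
    p = softmax(logits)
    B, T, K = p.shape
    m = mask.astype(bool)
    n = max(int(m.sum()), 1)
    rows, cols = np.nonzero(m)
    gold = targets[rows, cols]
    eps = 1e-12
    if kind in ("cce", "kl"):
        loss = float(-np.log(p[rows, cols, gold] + eps).sum() / n)
        dlogits = p.copy()
        dlogits[rows, cols, gold] -= 1.0
        dlogits *= m[:, :, None] / n
        return loss, dlogits
    if kind == "poisson":
        y = np.zeros_like(p)
        y[rows, cols, gold] = 1.0
        per_tok = (p - y * np.log(p + eps)).mean(axis=-1)
        loss = float(per_tok[m].sum() / n)
        dLdp = (1.0 - y / (p + eps)) / K
        inner = (p * dLdp).sum(axis=-1, keepdims=True)
        dlogits = p * (dLdp - inner)
        dlogits *= m[:, :, None] / n
        return loss, dlogits
    raise ValueError(f"unknown loss {kind!r}")


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class Optimizer:
    """Base: update a named set of (param, grad) arrays in place."""

    def __init__(self, lr: float = 1e-3, clip_norm: float | None = 5.0):
        self.lr = lr
        self.clip_norm = clip_norm
        self.t = 0
        self.state: dict[str, dict[str, np.ndarray]] = {}

    def _slot(self, name: str, like: np.ndarray, keys) -> dict:
        if name not in self.state:
            self.state[name] = {k: np.zeros_like(like) for k in keys}
        return self.state[name]

    def step(self, named_params) -> None:
        named_params = list(named_params)
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g ** 2).sum()) for _, _, g in named_params))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                for _, _, g in named_params:
                    g *= scale
        self.t += 1
        for name, p, g in named_params:
            self._update(name, p, g)

    def _update(self, name, p, g):  # pragma: no cover - abstract
        raise NotImplementedError


class RMSProp(Optimizer):
    def __init__(self, lr=1e-3, rho=0.9, eps=1e-8, clip_norm=5.0):
        super().__init__(lr, clip_norm)
        self.rho, self.eps = rho, eps

    def _update(self, name, p, g):
        s = self._slot(name, p, ["v"])
        s["v"][:] = self.rho * s["v"] + (1 - self.rho) * g * g
        p -= self.lr * g / (np.sqrt(s["v"]) + self.eps)


class Adam(Optimizer):
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, clip_norm=5.0):
        super().__init__(lr, clip_norm)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def _update(self, name, p, g):
        s = self._slot(name, p, ["m", "v"])
        b1, b2 = self.beta1, self.beta2
        s["m"][:] = b1 * s["m"] + (1 - b1) * g
        s["v"][:] = b2 * s["v"] + (1 - b2) * g * g
        mhat = s["m"] / (1 - b1 ** self.t)
        vhat = s["v"] / (1 - b2 ** self.t)
        p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Nadam(Adam):
    def _update(self, name, p, g):
        s = self._slot(name, p, ["m", "v"])
        b1, b2 = self.beta1, self.beta2
        s["m"][:] = b1 * s["m"] + (1 - b1) * g
        s["v"][:] = b2 * s["v"] + (1 - b2) * g * g
        mhat = s["m"] / (1 - b1 ** (self.t + 1))
        vhat = s["v"] / (1 - b2 ** self.t)
        # Nesterov look-ahead on the first moment
        update = b1 * mhat + (1 - b1) * g / (1 - b1 ** (self.t + 1))
        p -= self.lr * update / (np.sqrt(vhat) + self.eps)


OPTIMIZERS = {"rmsprop": RMSProp, "adam": Adam, "nadam": Nadam}
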