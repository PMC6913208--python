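"""Minimal NumPy neural-network primitives with explicit backpropagation.

Provides exactly what the layered tagger needs — embeddings, an LSTM cell
unrolled over a sequence, a bidirectional wrapper, a linear projection,
inverted dropout, and Adam.  Every ``forward`` returns a cache and every
``backward`` consumes it, accumulating parameter gradients in place
(``Param.grad``); gradient correctness is verified against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan = sum(shape[:2]) if len(shape) >= 2 else shape[0]
    scale = np.sqrt(6.0 / max(fan, 1))
    return rng.uniform(-scale, scale, size=shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


class Embedding:
    def __init__(self, name: str, n: int, dim: int, rng: np.random.Generator,
                 scale: float = 0.1):
        self.table = Param(name, rng.normal(0.0, scale, size=(n, dim)))
        self.params = [self.table]

    def forward(self, indices: list[int]) -> np.ndarray:
        return self.table.value[indices]

    def backward(self, indices: list[int], dout: np.ndarray) -> None:
        np.add.at(self.table.grad, indices, dout)

    def set_rows(self, rows: dict[int, np.ndarray]) -> None:
        for i, v in rows.items():
            self.table.value[i] = v


class Linear:
    def __init__(self, name: str, in_dim: int, out_dim: int,
                 rng: np.random.Generator):
        self.W = Param(f"{name}.W", glorot(rng, (in_dim, out_dim)))
        self.b = Param(f"{name}.b", np.zeros(out_dim))
        self.params = [self.W, self.b]

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return X @ self.W.value + self.b.value, X

    def backward(self, dY: np.ndarray, cache: np.ndarray) -> np.ndarray:
        self.W.grad += cache.T @ dY
        self.b.grad += dY.sum(axis=0)
        return dY @ self.W.value.T


class LSTM:
    """Unidirectional LSTM unrolled over a (T, D) input; gate order i,f,g,o."""

    def __init__(self, name: str, in_dim: int, hidden: int,
                 rng: np.random.Generator):
        self.hidden = hidden
        self.W = Param(f"{name}.W", glorot(rng, (in_dim, 4 * hidden)))
        self.U = Param(f"{name}.U", glorot(rng, (hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Param(f"{name}.b", b)
        self.params = [self.W, self.U, self.b]

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, dict]:
        T = X.shape[0]
        H = self.hidden
        h = np.zeros((T + 1, H))
        c = np.zeros((T + 1, H))
        gates = np.zeros((T, 4 * H))
        tanh_c = np.zeros((T, H))
        for t in range(T):
            z = X[t] @ self.W.value + h[t] @ self.U.value + self.b.value
            i = _sigmoid(z[:H])
            f = _sigmoid(z[H : 2 * H])
            g = np.tanh(z[2 * H : 3 * H])
            o = _sigmoid(z[3 * H :])
            c[t + 1] = f * c[t] + i * g
            tanh_c[t] = np.tanh(c[t + 1])
            h[t + 1] = o * tanh_c[t]
            gates[t] = np.concatenate([i, f, g, o])
        cache = {"X": X, "h": h, "c": c, "gates": gates, "tanh_c": tanh_c}
        return h[1:], cache

    def backward(self, dH: np.ndarray, cache: dict) -> np.ndarray:
        X, h, c = cache["X"], cache["h"], cache["c"]
        gates, tanh_c = cache["gates"], cache["tanh_c"]
        T = X.shape[0]
        H = self.hidden
        dX = np.zeros_like(X)
        dh_next = np.zeros(H)
        dc_next = np.zeros(H)
        for t in range(T - 1, -1, -1):
            i, f = gates[t, :H], gates[t, H : 2 * H]
            g, o = gates[t, 2 * H : 3 * H], gates[t, 3 * H :]
            dh = dH[t] + dh_next
            do = dh * tanh_c[t]
            dc = dh * o * (1 - tanh_c[t] ** 2) + dc_next
            di = dc * g
            df = dc * c[t]
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ])
            self.W.grad += np.outer(X[t], dz)
            self.U.grad += np.outer(h[t], dz)
            self.b.grad += dz
            dX[t] = dz @ self.W.value.T
            dh_next = dz @ self.U.value.T
        return dX


class BiLSTM:
    """Bidirectional LSTM: sequence output (T, 2H) or last-state vector (2H,).

    The last-state mode concatenates the forward pass's final hidden state
    with the backward pass's final state (which summarizes the sequence
    read right-to-left) — the standard recipe for character-level word
    embeddings.
    """

    def __init__(self, name: str, in_dim: int, hidden: int,
                 rng: np.random.Generator):
        self.hidden = hidden
        self.fwd = LSTM(f"{name}.fwd", in_dim, hidden, rng)
        self.bwd = LSTM(f"{name}.bwd", in_dim, hidden, rng)
        self.params = self.fwd.params + self.bwd.params

    def forward_seq(self, X: np.ndarray) -> tuple[np.ndarray, dict]:
        Hf, cf = self.fwd.forward(X)
        Hb_rev, cb = self.bwd.forward(X[::-1])
        out = np.concatenate([Hf, Hb_rev[::-1]], axis=1)
        return out, {"cf": cf, "cb": cb}

    def backward_seq(self, dOut: np.ndarray, cache: dict) -> np.ndarray:
        H = self.hidden
        dXf = self.fwd.backward(dOut[:, :H], cache["cf"])
        dXb = self.bwd.backward(dOut[::-1, H:], cache["cb"])
        return dXf + dXb[::-1]

    def forward_last(self, X: np.ndarray) -> tuple[np.ndarray, dict]:
        Hf, cf = self.fwd.forward(X)
        Hb_rev, cb = self.bwd.forward(X[::-1])
        out = np.concatenate([Hf[-1], Hb_rev[-1]])
        return out, {"cf": cf, "cb": cb, "T": X.shape[0]}

    def backward_last(self, dvec: np.ndarray, cache: dict) -> np.ndarray:
        H = self.hidden
        T = cache["T"]
        dHf = np.zeros((T, H))
        dHf[-1] = dvec[:H]
        dHb = np.zeros((T, H))
        dHb[-1] = dvec[H:]
        dXf = self.fwd.backward(dHf, cache["cf"])
        dXb = self.bwd.backward(dHb, cache["cb"])
        return dXf + dXb[::-1]


def dropout_mask(rng: np.random.Generator, shape: tuple[int, ...],
                 rate: float) -> np.ndarray:
    """Inverted-dropout mask; multiply by it in both passes."""
    if rate <= 0.0:
        return np.ones(shape)
    return (rng.random(shape) >= rate) / (1.0 - rate)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, clip: float | None = 5.0) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for k, p in enumerate(self.params):
            g = p.grad
            if clip is not None:
                norm = np.linalg.norm(g)
                if norm > clip:
                    g = g * (clip / norm)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            p.value -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
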