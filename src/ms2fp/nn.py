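"""A compact NumPy neural-network engine for multi-label prediction.

Implements exactly the pieces the fingerprint-prediction models need —
dense, 1-D convolution, max-pooling and LSTM layers, sigmoid multi-label
outputs, Adam, early stopping, and two losses (differentiable soft-Tanimoto
and binary cross-entropy) — with manual backpropagation.  Everything is
seeded and single-threaded-deterministic: two networks built and trained
with the same seed produce bit-identical parameters.

Shapes: dense layers carry ``(batch, features)``; convolution/LSTM layers
carry ``(batch, length, channels)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "Sigmoid",
    "Reshape1C",
    "Conv1D",
    "MaxPool1D",
    "Flatten",
    "Chunk",
    "LSTM",
    "SoftTanimotoLoss",
    "BCELoss",
    "Network",
    "TrainingDiverged",
]

_EPS = 1e-8


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


class Layer:
    """Base layer: parameter dicts plus forward/backward passes."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def init_params(self, rng: np.random.Generator):  # pragma: no cover - default
        pass

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot(rng, fan_in, fan_out, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out

    def init_params(self, rng):
        self.params = {
            "W": _glorot(rng, self.n_in, self.n_out, (self.n_in, self.n_out)),
            "b": np.zeros(self.n_out),
        }

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads = {"W": self._x.T @ g, "b": g.sum(axis=0)}
        return g @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Sigmoid(Layer):
    def forward(self, x):
        self._s = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._s

    def backward(self, g):
        return g * self._s * (1.0 - self._s)


class Reshape1C(Layer):
    """(batch, length) -> (batch, length, 1) for convolution stacks."""

    def forward(self, x):
        return x[:, :, None]

    def backward(self, g):
        return g[:, :, 0]


class Conv1D(Layer):
    """Valid-padding 1-D convolution, stride 1."""

    def __init__(self, in_channels: int, filters: int, width: int):
        super().__init__()
        self.in_channels, self.filters, self.width = in_channels, filters, width

    def init_params(self, rng):
        fan_in = self.width * self.in_channels
        self.params = {
            "W": _glorot(rng, fan_in, self.filters,
                         (self.width, self.in_channels, self.filters)),
            "b": np.zeros(self.filters),
        }

    def forward(self, x):
        # x: (B, L, C) -> windows (B, T, C, width), T = L - width + 1
        self._x = x
        win = np.lib.stride_tricks.sliding_window_view(x, self.width, axis=1)
        self._win = win
        return np.einsum("btcw,wcf->btf", win, self.params["W"]) + self.params["b"]

    def backward(self, g):
        self.grads = {
            "W": np.einsum("btcw,btf->wcf", self._win, g),
            "b": g.sum(axis=(0, 1)),
        }
        dx = np.zeros_like(self._x)
        T = g.shape[1]
        for w in range(self.width):
            # contribution of filter tap w to input positions w .. w+T-1
            dx[:, w : w + T, :] += np.einsum("btf,cf->btc", g, self.params["W"][w])
        return dx


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x):
        B, L, C = x.shape
        T = L // self.pool
        self._shape = x.shape
        xr = x[:, : T * self.pool, :].reshape(B, T, self.pool, C)
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, g):
        B, L, C = self._shape
        T = g.shape[1]
        dx = np.zeros((B, T, self.pool, C))
        b_idx, t_idx, c_idx = np.meshgrid(
            np.arange(B), np.arange(T), np.arange(C), indexing="ij"
        )
        dx[b_idx, t_idx, self._argmax, c_idx] = g
        out = np.zeros(self._shape)
        out[:, : T * self.pool, :] = dx.reshape(B, T * self.pool, C)
        return out


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Chunk(Layer):
    """(batch, length) -> (batch, steps, chunk) sequence for the LSTM;
    right-pads with zeros when length is not divisible by ``steps``."""

    def __init__(self, steps: int):
        super().__init__()
        self.steps = steps

    def forward(self, x):
        B, L = x.shape
        self._L = L
        chunk = -(-L // self.steps)  # ceil
        pad = self.steps * chunk - L
        if pad:
            x = np.concatenate([x, np.zeros((B, pad))], axis=1)
        return x.reshape(B, self.steps, chunk)

    def backward(self, g):
        return g.reshape(g.shape[0], -1)[:, : self._L]


class LSTM(Layer):
    """Single LSTM layer returning the final hidden state."""

    def __init__(self, n_in: int, hidden: int):
        super().__init__()
        self.n_in, self.hidden = n_in, hidden

    def init_params(self, rng):
        H = self.hidden
        self.params = {
            "Wx": _glorot(rng, self.n_in, 4 * H, (self.n_in, 4 * H)),
            "Wh": _glorot(rng, H, 4 * H, (H, 4 * H)),
            "b": np.zeros(4 * H),
        }
        self.params["b"][H : 2 * H] = 1.0  # forget-gate bias

    @staticmethod
    def _sigm(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def forward(self, x):
        B, T, F = x.shape
        H = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._cache = []
        for t in range(T):
            z = x[:, t, :] @ Wx + h @ Wh + b
            i = self._sigm(z[:, :H])
            f = self._sigm(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = self._sigm(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            self._cache.append((h, c, i, f, g, o, tanh_c))
            h, c = o * tanh_c, c_new
        return h

    def backward(self, grad_h):
        B, T, F = self._x.shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dx = np.zeros_like(self._x)
        dh = grad_h
        dc = np.zeros((B, H))
        for t in reversed(range(T)):
            h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            do = dh * tanh_c
            dct = dh * o * (1 - tanh_c**2) + dc
            di, dg, df = dct * g, dct * i, dct * c_prev
            dc = dct * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dWx += self._x[:, t, :].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ Wx.T
            dh = dz @ Wh.T
        self.grads = {"Wx": dWx, "Wh": dWh, "b": db}
        return dx


# --- losses -----------------------------------------------------------------


class SoftTanimotoLoss:
    """1 minus the differentiable Tanimoto (Jaccard) similarity.

    For a binary target y and predicted probabilities p the per-sample
    similarity is sum(y*p) / (sum(y) + sum(p) - sum(y*p)); on binary p this
    reduces to TP/(TP+FP+FN).  A sample with y and p both all-zero is scored
    loss 0 (perfect) by convention.
    """

    def value(self, Y, P):
        I = (Y * P).sum(axis=1)
        U = Y.sum(axis=1) + P.sum(axis=1) - I
        loss = np.where(U > _EPS, 1.0 - I / np.maximum(U, _EPS), 0.0)
        return float(loss.mean())

    def grad(self, Y, P):
        I = (Y * P).sum(axis=1, keepdims=True)
        U = Y.sum(axis=1, keepdims=True) + P.sum(axis=1, keepdims=True) - I
        Us = np.maximum(U, _EPS)
        g = -(Y * Us - I * (1.0 - Y)) / Us**2
        g[(U <= _EPS).ravel()] = 0.0
        return g / Y.shape[0]


class BCELoss:
    """Mean element-wise binary cross-entropy."""

    def value(self, Y, P):
        P = np.clip(P, 1e-7, 1 - 1e-7)
        return float(-(Y * np.log(P) + (1 - Y) * np.log(1 - P)).mean())

    def grad(self, Y, P):
        P = np.clip(P, 1e-7, 1 - 1e-7)
        return (P - Y) / (P * (1 - P)) / Y.size


# --- network ----------------------------------------------------------------


class Adam:
    """Adam with optional decoupled L2 decay and proximal L1 shrinkage.

    Both penalties act on weight matrices only (never biases).  The L1 term
    is applied as a proximal soft-threshold after the Adam step, which
    drives small weights exactly to zero; sparse first-layer weights are the
    appropriate prior when each output bit depends on a handful of input
    bins, as fragmentation fingerprint maps do.
    """

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay=0.0, l1=0.0):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.l1 = l1
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, layers):
        self.t += 1
        for li, layer in enumerate(layers):
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                key = (li, name)
                m = self.m.setdefault(key, np.zeros_like(p))
                v = self.v.setdefault(key, np.zeros_like(p))
                m[:] = self.b1 * m + (1 - self.b1) * g
                v[:] = self.b2 * v + (1 - self.b2) * g**2
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                if self.weight_decay and name != "b":
                    p -= self.lr * self.weight_decay * p
                if self.l1 and name != "b":
                    thresh = self.lr * self.l1
                    p[:] = np.sign(p) * np.maximum(np.abs(p) - thresh, 0.0)


class Network:
    """A sequential network with seeded initialization and early stopping."""

    def __init__(self, layers, loss=None, seed: int = 0):
        self.layers = list(layers)
        self.loss = loss or SoftTanimotoLoss()
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        for layer in self.layers:
            layer.init_params(rng)

    def forward(self, X):
        for layer in self.layers:
            X = layer.forward(X)
        return X

    predict = forward

    def _backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def fit(
        self,
        X,
        Y,
        epochs: int = 50,
        batch_size: int = 32,
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        l1: float = 0.0,
        validation: tuple | None = None,
        patience: int | None = 10,
        min_delta: float = 1e-5,
        shuffle: bool = True,
    ) -> list[dict]:
        """Train with Adam; returns the per-epoch history.

        ``validation`` is an optional ``(X_val, Y_val)`` pair used for early
        stopping (best weights restored).  Raises :class:`TrainingDiverged`
        on a non-finite loss.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        opt = Adam(lr=lr, weight_decay=weight_decay, l1=l1)
        rng = np.random.default_rng(self.seed + 1)
        history: list[dict] = []
        best_val = np.inf
        best_weights = None
        stale = 0
        n = X.shape[0]
        for epoch in range(epochs):
            order = rng.permutation(n) if shuffle else np.arange(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                P = self.forward(X[idx])
                batch_loss = self.loss.value(Y[idx], P)
                if not (np.isfinite(batch_loss) and np.isfinite(P).all()):
                    raise TrainingDiverged(
                        f"non-finite loss at epoch {epoch}, batch {n_batches}"
                    )
                self._backward(self.loss.grad(Y[idx], P))
                opt.step(self.layers)
                epoch_loss += batch_loss
                n_batches += 1
            record = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
            if validation is not None:
                Xv, Yv = validation
                val_loss = self.loss.value(np.asarray(Yv, dtype=float),
                                           self.forward(np.asarray(Xv, dtype=float)))
                record["val_loss"] = val_loss
                if val_loss < best_val - min_delta:
                    best_val = val_loss
                    best_weights = self.get_weights()
                    stale = 0
                else:
                    stale += 1
            history.append(record)
            if validation is not None and patience is not None and stale >= patience:
                break
        if best_weights is not None:
            self.set_weights(best_weights)
        return history

    def get_weights(self) -> dict[str, np.ndarray]:
        return {
            f"{li}:{name}": p.copy()
            for li, layer in enumerate(self.layers)
            for name, p in layer.params.items()
        }

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = weights[f"{li}:{name}"].copy()
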