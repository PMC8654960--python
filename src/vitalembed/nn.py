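"""A small, deterministic LSTM implemented on numpy.

One recurrent layer plus a linear (or sigmoid) output head read from the
final time step's hidden state.  This is the sequence model behind every
per-signal embedding: the embedding of a window is the final hidden state
with the head removed.  Training is full backprop-through-time with Adam
and gradient-norm clipping; all randomness (initialization, shuffling)
flows through explicit seeds, so a (seed, data) pair reproduces a model
bit for bit.

Only final-step losses are needed here: the *auto*/*next*/*min* targets
are all predicted from the last hidden state, so gradients enter the
recurrence solely at the last step and flow backwards through it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_GATES = 4  # input, forget, output (sigmoid block) then cell (tanh)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # clipping keeps exp in range; exact to float precision for |z| < 60
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


@dataclass
class LSTMNet:
    """Single-layer LSTM with a dense head on the last hidden state."""

    input_dim: int
    hidden_dim: int
    output_dim: int
    output_activation: str = "linear"   # "linear" | "sigmoid"
    seed: int = 0
    params: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.params:
            self.params = self._init_params()

    def _init_params(self) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(self.seed)
        H, I, O = self.hidden_dim, self.input_dim, self.output_dim
        k = 1.0 / np.sqrt(H)
        p = {
            "Wx": rng.uniform(-k, k, size=(I, _GATES * H)),
            "Wh": rng.uniform(-k, k, size=(H, _GATES * H)),
            "b": rng.uniform(-k, k, size=_GATES * H),
            "Wo": rng.uniform(-k, k, size=(H, O)),
            "bo": rng.uniform(-k, k, size=O),
        }
        # gate layout: [input, forget, output | cell]; sigmoid gates first
        p["b"][H : 2 * H] += 1.0  # forget-gate bias: remember by default
        return p

    # -- forward ----------------------------------------------------------

    def _recurrence(self, X: np.ndarray, keep_cache: bool):
        """X: (B, T, I) -> final hidden state (B, H), optional caches."""
        B, T, _ = X.shape
        H = self.hidden_dim
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = [] if keep_cache else None
        XW = X.reshape(B * T, -1) @ Wx  # hoist the input projection
        XW = XW.reshape(B, T, _GATES * H)
        for t in range(T):
            z = XW[:, t, :] + h @ Wh + b
            s = _sigmoid(z[:, : 3 * H])  # input, forget, output in one call
            i = s[:, :H]
            f = s[:, H : 2 * H]
            o = s[:, 2 * H :]
            g = np.tanh(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            if keep_cache:
                cache.append((i, f, g, o, c_prev, tc, h_prev))
        return h, cache

    def hidden(self, X: np.ndarray) -> np.ndarray:
        """Final-time-step hidden state (the embedding), (B, H)."""
        X = self._check_input(X)
        h, _ = self._recurrence(X, keep_cache=False)
        return h

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Head output: logits for sigmoid heads, values for linear ones."""
        h = self.hidden(X)
        return h @ self.params["Wo"] + self.params["bo"]

    def predict(self, X: np.ndarray) -> np.ndarray:
        y = self.forward(X)
        if self.output_activation == "sigmoid":
            return _sigmoid(y)
        return y

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:  # (B, T) single-channel convenience
            X = X[:, :, None]
        if X.shape[-1] != self.input_dim:
            raise ValueError(
                f"expected {self.input_dim} input channel(s), got {X.shape[-1]}"
            )
        return X

    # -- loss and gradients ------------------------------------------------

    def loss(self, X: np.ndarray, Y: np.ndarray) -> float:
        return self._loss_and_grads(X, Y, want_grads=False)[0]

    def _loss_and_grads(self, X, Y, want_grads=True):
        X = self._check_input(X)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        B = X.shape[0]
        h_T, cache = self._recurrence(X, keep_cache=want_grads)
        logits = h_T @ self.params["Wo"] + self.params["bo"]
        if self.output_activation == "sigmoid":
            # numerically safe binary cross entropy on logits
            L = float(
                np.mean(
                    np.maximum(logits, 0)
                    - logits * Y
                    + np.log1p(np.exp(-np.abs(logits)))
                )
            )
            dlogits = (_sigmoid(logits) - Y) / Y.size
        else:
            diff = logits - Y
            L = float(np.mean(diff**2))
            dlogits = 2.0 * diff / Y.size
        if not want_grads:
            return L, None
        H = self.hidden_dim
        Wh, Wo = self.params["Wh"], self.params["Wo"]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["Wo"] = h_T.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dh = dlogits @ Wo.T
        dc = np.zeros((B, H))
        T = X.shape[1]
        dz_all = np.empty((B, T, _GATES * H))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc**2)
            dz = dz_all[:, t, :]
            np.multiply(dc * g, i * (1.0 - i), out=dz[:, :H])
            np.multiply(dc * c_prev, f * (1.0 - f), out=dz[:, H : 2 * H])
            np.multiply(do, o * (1.0 - o), out=dz[:, 2 * H : 3 * H])
            np.multiply(dc * i, 1.0 - g**2, out=dz[:, 3 * H :])
            grads["Wh"] += h_prev.T @ dz
            dh = dz @ Wh.T
            dc = dc * f
        grads["b"] = dz_all.sum(axis=(0, 1))
        grads["Wx"] = X.reshape(B * T, -1).T @ dz_all.reshape(B * T, -1)
        return L, grads

    def copy(self) -> "LSTMNet":
        return LSTMNet(
            input_dim=self.input_dim,
            hidden_dim=self.hidden_dim,
            output_dim=self.output_dim,
            output_activation=self.output_activation,
            seed=self.seed,
            params={k: v.copy() for k, v in self.params.items()},
        )

    def weight_digest(self) -> str:
        """Hex digest of all parameters (change detector for tests)."""
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.hexdigest()


class Adam:
    """Adam with global gradient-norm clipping."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float = 5.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
        scale = min(1.0, self.clip_norm / (norm + 1e-12))
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            g = g * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            self.params[k] -= self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps
            )
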