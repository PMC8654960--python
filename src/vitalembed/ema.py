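"""Non-neural per-signal embeddings: identity (*raw*) and exponential
moving average / variance (*ema*).

The EMA recursion over a window ``x[0..T-1]`` is

    EMA_0 = x[0]
    EMA_t = alpha * x[t] + (1 - alpha) * EMA_{t-1}

and the exponential moving variance shares the same EMA state:

    delta_t = x[t] - EMA_{t-1}
    EMA_t   = EMA_{t-1} + alpha * delta_t          (same update, rearranged)
    EMV_t   = (1 - alpha) * (EMV_{t-1} + alpha * delta_t**2),   EMV_0 = 0

The default *ema* embedding of a 60-minute window is the 4-vector
``(EMA(alpha=0.1), EMA(alpha=1), EMA(alpha=5), EMV(alpha=5))``.

``alpha = 5`` applied literally gives sign-alternating weights (the
recursion is still perfectly well defined and deterministic); it most
likely originated as a span/decay parameter in the feature-engineering
tradition this embedding comes from.  Both readings are offered:
``literal_mode=True`` (default) runs the recursion verbatim for any
alpha, while span mode reinterprets alpha > 1 as a span, substituting the
smoothing factor ``2 / (alpha + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import HISTORY_LEN


@dataclass(frozen=True)
class EmaParams:
    alphas_ema: tuple[float, ...] = (0.1, 1.0, 5.0)
    alphas_emv: tuple[float, ...] = (5.0,)
    literal_mode: bool = True

    def __post_init__(self) -> None:
        if not self.alphas_ema and not self.alphas_emv:
            raise ValueError("at least one alpha required")

    @property
    def dim(self) -> int:
        return len(self.alphas_ema) + len(self.alphas_emv)


def _effective_alpha(alpha: float, literal_mode: bool) -> float:
    if not literal_mode and alpha > 1:
        return 2.0 / (alpha + 1.0)
    return alpha


def embed_raw(history: np.ndarray) -> np.ndarray:
    """Identity embedding of a 60-minute window (returned as a copy)."""
    history = np.asarray(history, dtype=float)
    if history.shape[-1] != HISTORY_LEN:
        raise ValueError(f"expected a {HISTORY_LEN}-minute window")
    return history.copy()


def ema(history: np.ndarray, alpha: float, literal_mode: bool = True) -> float:
    """Exponential moving average of a window, evaluated at the last index."""
    x = np.asarray(history, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty window")
    a = _effective_alpha(alpha, literal_mode)
    v = x[0]
    for t in range(1, x.size):
        v = a * x[t] + (1.0 - a) * v
    return float(v)


def emv(history: np.ndarray, alpha: float, literal_mode: bool = True) -> float:
    """Exponential moving variance at the last index (EMV_0 = 0)."""
    x = np.asarray(history, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty window")
    a = _effective_alpha(alpha, literal_mode)
    ema_state = x[0]
    emv_state = 0.0
    for t in range(1, x.size):
        delta = x[t] - ema_state
        ema_state = ema_state + a * delta
        emv_state = (1.0 - a) * (emv_state + a * delta * delta)
    return float(emv_state)


def embed_ema(history: np.ndarray, params: EmaParams | None = None) -> np.ndarray:
    """EMA/EMV feature vector of one 60-minute window (default dim 4)."""
    params = params or EmaParams()
    x = np.asarray(history, dtype=float)
    if x.shape[-1] != HISTORY_LEN:
        raise ValueError(f"expected a {HISTORY_LEN}-minute window")
    feats = [ema(x, a, params.literal_mode) for a in params.alphas_ema]
    feats += [emv(x, a, params.literal_mode) for a in params.alphas_emv]
    return np.array(feats)


def embed_ema_batch(
    histories: np.ndarray, params: EmaParams | None = None
) -> np.ndarray:
    """Vectorized :func:`embed_ema` over an (n, 60) batch -> (n, dim)."""
    params = params or EmaParams()
    X = np.asarray(histories, dtype=float)
    if X.ndim != 2 or X.shape[1] != HISTORY_LEN:
        raise ValueError(f"expected (n, {HISTORY_LEN}) batch")
    n, T = X.shape
    cols = []
    for a_raw in params.alphas_ema:
        a = _effective_alpha(a_raw, params.literal_mode)
        v = X[:, 0].copy()
        for t in range(1, T):
            v = a * X[:, t] + (1.0 - a) * v
        cols.append(v)
    for a_raw in params.alphas_emv:
        a = _effective_alpha(a_raw, params.literal_mode)
        ema_state = X[:, 0].copy()
        emv_state = np.zeros(n)
        for t in range(1, T):
            delta = X[:, t] - ema_state
            ema_state = ema_state + a * delta
            emv_state = (1.0 - a) * (emv_state + a * delta * delta)
        cols.append(emv_state)
    return np.stack(cols, axis=1)
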