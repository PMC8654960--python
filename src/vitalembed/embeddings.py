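"""Per-signal sequence-embedding models and their training tasks.

Five tasks define what the upstream LSTM learns from a 60-minute window:

=========  ==========================================  =====
task       target                                      loss
=========  ==========================================  =====
``rand``   none (random weights, never trained)        —
``auto``   the 60-minute window itself                 MSE
``next``   the next 5 minutes of the same signal       MSE
``min``    the minimum of the next 5 minutes           MSE
``hypo``   the downstream binary outcome               BCE
=========  ==========================================  =====

``auto``/``next``/``min`` are self-supervised: their targets come from the
signal itself, so a source hospital can train them without outcome labels
and ship the model.  The embedding of a window is the final hidden state
of the trained LSTM (the output head is dropped), 200-dimensional by
default.  Inputs — and the self-supervised regression targets, to keep MSE
scales comparable across signals — are standardized with the model's own
training-set statistics, which travel with the model so that a foreign
site can apply it without access to the source data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import FUTURE_LEN, HISTORY_LEN
from .nn import Adam, LSTMNet

TASKS = ("rand", "auto", "next", "min", "hypo")

#: task -> (output head size per channel, loss, activation)
_TASK_SPEC = {
    "rand": (1, "none", "linear"),
    "auto": (HISTORY_LEN, "mse", "linear"),
    "next": (FUTURE_LEN, "mse", "linear"),
    "min": (1, "mse", "linear"),
    "hypo": (1, "bce", "sigmoid"),
}


def task_targets(
    task: str,
    histories: np.ndarray,
    futures: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> np.ndarray | None:
    """Training target per Table of tasks; arrays are (n, T) or (n, T, V)."""
    if task == "rand":
        return None
    if task == "auto":
        return histories.reshape(histories.shape[0], -1)
    if task == "next":
        if futures is None:
            raise ValueError("next task needs futures")
        return futures.reshape(futures.shape[0], -1)
    if task == "min":
        if futures is None:
            raise ValueError("min task needs futures")
        if futures.ndim == 3:
            return futures.min(axis=-1).reshape(futures.shape[0], -1)
        return futures.min(axis=1, keepdims=True)
    if task == "hypo":
        if labels is None:
            raise ValueError("hypo task needs downstream labels")
        return np.asarray(labels, dtype=float).reshape(-1, 1)
    raise ValueError(f"unknown task {task!r}; known: {TASKS}")


@dataclass
class TrainConfig:
    max_epochs: int = 30
    patience: int = 5
    batch_size: int = 128
    learning_rate: float = 1e-2
    seed: int = 0
    clip_norm: float = 5.0

    def __post_init__(self) -> None:
        if self.max_epochs < 0:   # 0 = no-op training (warm-start passthrough)
            raise ValueError("max_epochs must be >= 0")
        if min(self.patience, self.batch_size) < 1:
            raise ValueError("patience and batch size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class EmbeddingModel:
    """A (possibly multi-signal) sequence embedding model with provenance.

    ``signal_name`` is one variable name, or a tuple of names for the
    jointly trained multi-signal variant.  ``source_tag`` records the full
    provenance chain (``"OR1"``, or ``"OR1->OR0"`` after fine-tuning).
    ``norm`` holds the (mean, sd) of each input channel from the model's
    own training split; extraction always standardizes with these.
    """

    signal_name: str | tuple[str, ...]
    task: str
    source_tag: str
    embedding_dim: int
    net: LSTMNet
    norm: dict[str, tuple[float, float]] = field(default_factory=dict)
    training_meta: dict = field(default_factory=dict)

    @property
    def signals(self) -> tuple[str, ...]:
        if isinstance(self.signal_name, str):
            return (self.signal_name,)
        return tuple(self.signal_name)

    @property
    def is_joint(self) -> bool:
        return not isinstance(self.signal_name, str)

    def standardize(self, histories: np.ndarray) -> np.ndarray:
        """Apply the model's own normalization to raw-scale inputs.

        (n, 60) for single-signal models, (n, V, 60) for joint models
        (channel order = ``self.signals``).  Missing entries are imputed
        with the model's training mean first.
        """
        X = np.asarray(histories, dtype=float)
        if not self.is_joint:
            m, s = self.norm.get(self.signals[0], (0.0, 1.0))
            X = np.where(np.isnan(X), m, X)
            return (X - m) / s
        out = np.empty_like(X)
        for k, name in enumerate(self.signals):
            m, s = self.norm.get(name, (0.0, 1.0))
            col = np.where(np.isnan(X[:, k, :]), m, X[:, k, :])
            out[:, k, :] = (col - m) / s
        return out


def build_model(
    signal_name: str | tuple[str, ...],
    task: str,
    embedding_dim: int = 200,
    seed: int = 0,
    source_tag: str = "",
) -> EmbeddingModel:
    """Untrained model with a task-appropriate head; final for ``rand``."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; known: {TASKS}")
    joint = not isinstance(signal_name, str)
    n_channels = len(signal_name) if joint else 1
    head_per_channel, _, activation = _TASK_SPEC[task]
    out_dim = head_per_channel * (n_channels if task in ("auto", "next", "min") else 1)
    net = LSTMNet(
        input_dim=n_channels,
        hidden_dim=embedding_dim,
        output_dim=out_dim,
        output_activation=activation,
        seed=seed,
    )
    return EmbeddingModel(
        signal_name=tuple(signal_name) if joint else signal_name,
        task=task,
        source_tag=source_tag,
        embedding_dim=embedding_dim,
        net=net,
        training_meta={"seed": seed, "epochs_run": 0},
    )


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_embedding(
    model: EmbeddingModel,
    train_X: np.ndarray,
    train_Y: np.ndarray,
    val_X: np.ndarray,
    val_Y: np.ndarray,
    config: TrainConfig | None = None,
) -> EmbeddingModel:
    """Minimize the task loss; return the best-validation checkpoint.

    ``train_X``/``val_X`` are standardized inputs, (n, 60) or (n, 60, V)
    for joint models; targets come from :func:`task_targets`.  Validation
    loss is tracked every epoch; training stops after ``patience`` epochs
    without improvement and the weights with the lowest validation loss
    are restored.  The full training curve is kept in ``training_meta``.
    """
    if model.task == "rand":
        raise ValueError("rand models are never trained")
    if len(train_X) == 0:
        raise ValueError("empty training set")
    config = config or TrainConfig()
    net = model.net
    opt = Adam(net.params, lr=config.learning_rate, clip_norm=config.clip_norm)
    rng = np.random.default_rng(config.seed)
    curve: list[tuple[float, float]] = []
    best_val = net.loss(val_X, val_Y)
    best_params = {k: v.copy() for k, v in net.params.items()}
    best_epoch = 0
    since_best = 0
    for epoch in range(1, config.max_epochs + 1):
        train_losses = []
        for idx in _epoch_batches(len(train_X), config.batch_size, rng):
            L, grads = net._loss_and_grads(train_X[idx], train_Y[idx])
            if not np.isfinite(L):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(task={model.task}, signal={model.signal_name})"
                )
            opt.step(grads)
            train_losses.append(L)
        val_loss = net.loss(val_X, val_Y)
        curve.append((float(np.mean(train_losses)), float(val_loss)))
        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in net.params.items()}
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    net.params = best_params
    model.training_meta.update(
        {
            "epochs_run": len(curve),
            "best_epoch": best_epoch,
            "best_val_loss": float(best_val),
            "curve": curve,
            "seed": config.seed,
        }
    )
    return model


def fine_tune(
    pretrained: EmbeddingModel,
    target_tag: str,
    train_X: np.ndarray,
    train_Y: np.ndarray,
    val_X: np.ndarray,
    val_Y: np.ndarray,
    config: TrainConfig | None = None,
) -> EmbeddingModel:
    """Continue training a pretrained model on target-site data.

    The returned model starts from the pretrained weights, keeps the
    pretrained normalization statistics (the target site standardizes
    through the foreign model's own stats), and extends the provenance
    chain to ``"source->target"``.  ``max_epochs=0`` in the config yields
    an unchanged copy.
    """
    model = EmbeddingModel(
        signal_name=pretrained.signal_name,
        task=pretrained.task,
        source_tag=f"{pretrained.source_tag}->{target_tag}",
        embedding_dim=pretrained.embedding_dim,
        net=pretrained.net.copy(),
        norm=dict(pretrained.norm),
        training_meta={"initialized_from": pretrained.source_tag},
    )
    config = config or TrainConfig()
    if config.max_epochs == 0:
        model.training_meta.update({"epochs_run": 0, "curve": []})
        return model
    return train_embedding(model, train_X, train_Y, val_X, val_Y, config)


def extract(model: EmbeddingModel, histories: np.ndarray,
            standardized: bool = True) -> np.ndarray:
    """Embedding = final hidden state of the recurrent layer, (n, dim).

    Input arity must match the model: (n, 60) for per-signal models,
    (n, V, 60) with V == number of the model's channels for joint ones.
    Pass ``standardized=False`` to feed raw-scale values and have the
    model apply its own normalization.
    """
    X = np.asarray(histories, dtype=float)
    if not standardized:
        X = model.standardize(X)
    if model.is_joint:
        if X.ndim != 3 or X.shape[1] != len(model.signals):
            raise ValueError(
                f"joint model expects (n, {len(model.signals)}, {HISTORY_LEN})"
            )
        X = np.swapaxes(X, 1, 2)  # (n, T, V)
    else:
        if X.ndim != 2 or X.shape[1] != HISTORY_LEN:
            raise ValueError(f"per-signal model expects (n, {HISTORY_LEN})")
    return model.net.hidden(X)


# ---------------------------------------------------------------------------
# Bundles: a model + manifest in one .npz archive, so a model trained at one
# site can be applied at another without the source data.
# ---------------------------------------------------------------------------

def save_bundle(model: EmbeddingModel, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "signal_name": list(model.signals) if model.is_joint else model.signal_name,
        "joint": model.is_joint,
        "task": model.task,
        "source_tag": model.source_tag,
        "embedding_dim": model.embedding_dim,
        "input_dim": model.net.input_dim,
        "output_dim": model.net.output_dim,
        "output_activation": model.net.output_activation,
        "seed": model.net.seed,
        "norm": {k: list(v) for k, v in model.norm.items()},
        "training_meta": {
            k: v for k, v in model.training_meta.items() if k != "curve"
        },
    }
    arrays = {f"param_{k}": v for k, v in model.net.params.items()}
    np.savez(path, manifest=json.dumps(manifest), **arrays)
    return path


def load_bundle(path: str | Path) -> EmbeddingModel:
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(str(data["manifest"]))
        params = {
            k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")
        }
    net = LSTMNet(
        input_dim=manifest["input_dim"],
        hidden_dim=manifest["embedding_dim"],
        output_dim=manifest["output_dim"],
        output_activation=manifest["output_activation"],
        seed=manifest["seed"],
        params=params,
    )
    name = manifest["signal_name"]
    return EmbeddingModel(
        signal_name=tuple(name) if manifest["joint"] else name,
        task=manifest["task"],
        source_tag=manifest["source_tag"],
        embedding_dim=manifest["embedding_dim"],
        net=net,
        norm={k: (float(a), float(b)) for k, (a, b) in manifest["norm"].items()},
        training_meta=dict(manifest["training_meta"]),
    )


# ---------------------------------------------------------------------------
# Convenience: train one per-signal model straight from window sets.
# ---------------------------------------------------------------------------

def train_signal_embedding(
    signal: str,
    task: str,
    train_hist: np.ndarray,
    train_fut: np.ndarray,
    val_hist: np.ndarray,
    val_fut: np.ndarray,
    mean: float,
    sd: float,
    source_tag: str,
    embedding_dim: int = 200,
    labels: tuple[np.ndarray, np.ndarray] | None = None,
    config: TrainConfig | None = None,
) -> EmbeddingModel:
    """Build + train one per-signal model from raw-scale (n, 60)/(n, 5) arrays.

    Histories *and* self-supervised targets are standardized with the
    supplied training-split mean/sd; ``labels`` supplies (train, val)
    binary outcomes for the ``hypo`` task.
    """
    config = config or TrainConfig()
    model = build_model(signal, task, embedding_dim, seed=config.seed,
                        source_tag=source_tag)
    model.norm = {signal: (float(mean), float(sd))}
    if task == "rand":
        return model

    def std(a: np.ndarray) -> np.ndarray:
        a = np.where(np.isnan(a), mean, a)
        return (a - mean) / sd

    tX, vX = std(train_hist), std(val_hist)
    if task == "hypo":
        if labels is None:
            raise ValueError("hypo task needs (train, val) labels")
        tY = task_targets(task, tX, labels=labels[0])
        vY = task_targets(task, vX, labels=labels[1])
    else:
        tY = task_targets(task, tX, futures=std(train_fut))
        vY = task_targets(task, vX, futures=std(val_fut))
    return train_embedding(model, tX, tY, vX, vY, config)


def train_joint_model(
    signals: tuple[str, ...],
    train_hist: np.ndarray,
    train_fut: np.ndarray,
    val_hist: np.ndarray,
    val_fut: np.ndarray,
    norm: dict[str, tuple[float, float]],
    source_tag: str,
    embedding_dim: int = 200,
    config: TrainConfig | None = None,
) -> EmbeddingModel:
    """One LSTM over all input channels, forecasting all their next 5 minutes.

    ``train_hist`` is raw-scale (n, V, 60) and ``train_fut`` (n, V, 5) in
    ``signals`` order; the output head has 5 x V units.  Extraction still
    yields a single ``embedding_dim`` vector shared by all signals.
    """
    missing = [s for s in signals if s not in norm]
    if missing:
        raise ValueError(f"missing input channels in norm stats: {missing}")
    config = config or TrainConfig()
    model = build_model(tuple(signals), "next", embedding_dim,
                        seed=config.seed, source_tag=source_tag)
    model.norm = {s: norm[s] for s in signals}

    def std_h(a):  # (n, V, 60) -> (n, T, V) standardized
        return np.swapaxes(model.standardize(a), 1, 2)

    def std_f(a):  # (n, V, 5) flattened target
        out = np.empty_like(a)
        for k, s in enumerate(signals):
            m, sdv = norm[s]
            col = np.where(np.isnan(a[:, k, :]), m, a[:, k, :])
            out[:, k, :] = (col - m) / sdv
        return out.reshape(a.shape[0], -1)

    return train_embedding(
        model, std_h(train_hist), std_f(train_fut),
        std_h(val_hist), std_f(val_fut), config,
    )
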