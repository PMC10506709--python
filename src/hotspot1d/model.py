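"""The hot-spot window classifier: a three-block 1-D CNN.

Architecture (default depth 3): for each block, a same-padded 1-D convolution
over the window axis (64, 16, 4 filters with kernels 7, 5, 3), ReLU, and max
pooling of size 2; then a single dropout (0.5), flatten, a dense layer of 8
units, and one sigmoid output.  Loss is binary cross-entropy under RMSprop.
Training early-stops on validation F1 (threshold 0.5) and restores the best
checkpoint.

Depth is configurable in 2..5: layers added beyond three are copies of the
middle block (16 filters, kernel 5); at depth 2 that middle block is removed,
so the entry (64/7) and exit (4/3) blocks always bracket the stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

from . import nn
from .evaluation import confusion, metrics
from .windowing import WindowDataset

__all__ = ["CNN1DConfig", "TrainingResult", "resolve_depth", "build_model", "train", "predict", "save_model", "load_model"]

_BASE_FILTERS = (64, 16, 4)
_BASE_KERNELS = (7, 5, 3)
_MIDDLE = 1  # index of the block copied (depth > 3) or dropped (depth 2)


@dataclass(frozen=True)
class CNN1DConfig:
    """Hyperparameters of the window classifier.

    ``filters``/``kernel_sizes`` of None means "derive from n_conv_layers via
    the copy-the-middle-block rule".  Epoch budget, patience and batch size
    are surfaced here because they are not implied by the architecture.
    """

    n_conv_layers: int = 3
    filters: tuple[int, ...] | None = None
    kernel_sizes: tuple[int, ...] | None = None
    pool_size: int = 2
    activation: str = "relu"
    dropout_rate: float = 0.5
    dense_units: int = 8
    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 20
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conv_layers not in (2, 3, 4, 5):
            raise ValueError("n_conv_layers must be in {2, 3, 4, 5}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if (self.filters is None) != (self.kernel_sizes is None):
            raise ValueError("give both filters and kernel_sizes, or neither")
        if self.filters is not None:
            if len(self.filters) != self.n_conv_layers or len(self.kernel_sizes) != self.n_conv_layers:
                raise ValueError(
                    f"filters/kernel_sizes must each have n_conv_layers={self.n_conv_layers} entries"
                )


def resolve_depth(cfg: CNN1DConfig) -> CNN1DConfig:
    """Fill in per-layer filters/kernels for the requested depth.

    Depth 3 is the canonical (64, 16, 4) / (7, 5, 3) stack; deeper variants
    insert copies of the middle block, depth 2 removes it.  Explicit
    filter/kernel lists pass through untouched (lengths already validated).
    """
    if cfg.filters is not None:
        return cfg
    filters, kernels = list(_BASE_FILTERS), list(_BASE_KERNELS)
    extra = cfg.n_conv_layers - 3
    if extra >= 0:
        for _ in range(extra):
            filters.insert(_MIDDLE, _BASE_FILTERS[_MIDDLE])
            kernels.insert(_MIDDLE, _BASE_KERNELS[_MIDDLE])
    else:  # depth 2: drop the middle block
        del filters[_MIDDLE], kernels[_MIDDLE]
    return replace(cfg, filters=tuple(filters), kernel_sizes=tuple(kernels))


def _pooled_lengths(width: int, cfg: CNN1DConfig) -> list[int]:
    lengths = []
    length = width
    for _ in range(cfg.n_conv_layers):
        length //= cfg.pool_size
        lengths.append(length)
    return lengths


def build_model(cfg: CNN1DConfig, input_shape: tuple[int, int]) -> nn.Network:
    """Construct the network for windows of shape (w, D).

    Raises when pooling would collapse the window axis to length 0 before
    the last block, naming the minimum usable width.
    """
    cfg = resolve_depth(cfg)
    w, d = input_shape
    lengths = _pooled_lengths(w, cfg)
    if lengths[-1] < 1:
        raise ValueError(
            f"window width {w} too short for {cfg.n_conv_layers} pooling blocks of "
            f"size {cfg.pool_size}; need w >= {cfg.pool_size ** cfg.n_conv_layers}"
        )
    rng = np.random.default_rng(cfg.seed)
    layers: list[nn.Layer] = []
    c_in = d
    for n_filt, kernel in zip(cfg.filters, cfg.kernel_sizes):
        layers += [
            nn.Conv1DSame(kernel, c_in, n_filt, rng),
            nn.Activation(cfg.activation),
            nn.MaxPool1D(cfg.pool_size),
        ]
        c_in = n_filt
    layers += [
        nn.Dropout(cfg.dropout_rate),
        nn.Flatten(),
        nn.Dense(lengths[-1] * c_in, cfg.dense_units, rng),
        nn.Activation(cfg.activation),
        nn.Dense(cfg.dense_units, 1, rng),
    ]
    return nn.Network(layers)


@dataclass
class TrainingResult:
    """Per-epoch history plus the best (early-stopped) checkpoint."""

    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_f1: float = 0.0
    model: nn.Network | None = None


def _val_f1(model: nn.Network, val: WindowDataset, threshold: float = 0.5) -> float:
    scores = model.predict_proba(val.X)
    report = metrics(confusion(val.y, (scores >= threshold).astype(int)))
    return report.f1 if report.f1 is not None else 0.0


def train(
    model: nn.Network,
    train_set: WindowDataset,
    validation: WindowDataset,
    cfg: CNN1DConfig,
    class_weights: dict[int, float] | None = None,
) -> TrainingResult:
    """Mini-batch RMSprop training with early stopping on validation F1.

    After every epoch the validation F1 at threshold 0.5 is recorded; the
    best-scoring weights are checkpointed and training stops once
    ``cfg.patience`` epochs pass without strict improvement.  The model is
    left holding the best weights.  Fully deterministic under ``cfg.seed``.
    ``class_weights`` (from :func:`~hotspot1d.assembly.compute_class_weights`)
    switches on the cost-sensitive alternative to oversampling.
    """
    if len(train_set) == 0 or len(validation) == 0:
        raise ValueError("train and validation sets must be non-empty (early stopping needs both)")
    if train_set.X.shape[1:] != validation.X.shape[1:]:
        raise ValueError("train/validation window shapes differ")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    optimizer = nn.RMSprop(model.params, lr=cfg.learning_rate)
    weights_vec = None
    if class_weights is not None:
        weights_vec = np.where(train_set.y == 1, class_weights[1], class_weights[0])

    result = TrainingResult()
    best_weights = model.get_weights()
    x64 = train_set.X.astype(np.float64)
    y = train_set.y.astype(np.float64)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_set))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(x64[idx], train=True, rng=rng)
            sw = None if weights_vec is None else weights_vec[idx]
            loss, dlogit = nn.weighted_bce_and_grad(logits, y[idx], sw)
            model.backward(dlogit)
            optimizer.step(model.grads)
            epoch_loss += loss * len(idx)
        val_scores = model.predict_proba(validation.X)
        rep = metrics(confusion(validation.y, (val_scores >= 0.5).astype(int)))
        f1 = rep.f1 if rep.f1 is not None else 0.0
        result.history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / len(train_set),
                "val_precision": rep.precision,
                "val_recall": rep.recall,
                "val_f1": f1,
            }
        )
        if f1 > result.best_val_f1 or result.best_epoch < 0:
            result.best_val_f1 = f1
            result.best_epoch = epoch
            best_weights = model.get_weights()
        elif epoch - result.best_epoch > cfg.patience:
            break
    model.set_weights(best_weights)
    result.model = model
    return result


def predict(
    model: nn.Network, X: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Sigmoid scores in [0, 1] and thresholded labels (score >= threshold)."""
    X = np.asarray(X)
    if X.ndim != 3:
        raise ValueError(f"X must be (N, w, D), got shape {X.shape}")
    scores = model.predict_proba(X)
    return scores, (scores >= threshold).astype(np.int8)


def save_model(path: str | Path, model: nn.Network, cfg: CNN1DConfig, input_shape: tuple[int, int]) -> None:
    """Checkpoint weights + config to a single .npz."""
    cfg = resolve_depth(cfg)
    meta = json.dumps({"config": asdict(cfg), "input_shape": list(input_shape)})
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(path, meta=np.array(meta), **arrays)


def load_model(path: str | Path) -> tuple[nn.Network, CNN1DConfig, tuple[int, int]]:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
        cfg_d = meta["config"]
        cfg_d["filters"] = tuple(cfg_d["filters"])
        cfg_d["kernel_sizes"] = tuple(cfg_d["kernel_sizes"])
        cfg = CNN1DConfig(**cfg_d)
        input_shape = tuple(meta["input_shape"])
        model = build_model(cfg, input_shape)
        weights = [npz[f"w{i}"] for i in range(len(model.params))]
    model.set_weights(weights)
    return model, cfg, input_shape


def architecture_summary(cfg: CNN1DConfig, input_shape: tuple[int, int]) -> dict:
    """Shapes and parameter count without training (fingerprint for logs)."""
    cfg = resolve_depth(cfg)
    model = build_model(cfg, input_shape)
    return {
        "filters": list(cfg.filters),
        "kernel_sizes": list(cfg.kernel_sizes),
        "pooled_lengths": _pooled_lengths(input_shape[0], cfg),
        "n_params": model.n_params(),
    }
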