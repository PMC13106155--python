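"""Training protocol: SGD with momentum, cosine decay, repeated paired runs.

The full-scale protocol (defaults of :class:`TrainConfig`) is mini-batch
SGD with momentum 0.95, weight decay 1e-3, initial learning rate 1e-2
decayed per epoch on a cosine schedule, batch size 64, 300 epochs,
cross-entropy loss.  ``desk_train_config`` is the reduced preset used for
CPU-scale experiments on the synthetic phantoms.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .backbone import SwinTransformer
from .data import DatasetSplit, LabeledImage, label_index, normalize_standardize, resize_image
from .evaluation import MetricsReport, evaluate_predictions
from .nn import SGD, Tensor, log_softmax

__all__ = [
    "TrainConfig",
    "TrainLog",
    "TrainingDiverged",
    "cosine_lr",
    "cross_entropy",
    "prepare_arrays",
    "fit",
    "evaluate_model",
    "run_repeated",
    "desk_train_config",
]


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 1e-2
    momentum: float = 0.95
    weight_decay: float = 1e-3
    batch_size: int = 64
    epochs: int = 300
    seed: int = 0
    schedule: str = "cosine"
    image_size: int = 224

    def __post_init__(self):
        if min(self.lr0, self.batch_size, self.epochs) <= 0 or self.weight_decay < 0:
            raise ValueError("training hyperparameters must be positive")


def desk_train_config(seed: int = 0, epochs: int = 20) -> TrainConfig:
    """Reduced-problem preset matching the 56x56 phantom task."""
    return TrainConfig(lr0=5e-3, momentum=0.9, weight_decay=1e-3,
                       batch_size=32, epochs=epochs, seed=seed, image_size=56)


@dataclass
class TrainLog:
    records: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class TrainingDiverged(RuntimeError):
    pass


def cosine_lr(epoch: int, total_epochs: int, lr0: float) -> float:
    """``lr(t) = 0.5 * lr0 * (1 + cos(pi * t / T))``; lr0 at t=0, 0 at t=T."""
    if not 0 <= epoch <= total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs}]")
    return 0.5 * lr0 * (1.0 + np.cos(np.pi * epoch / total_epochs))


def cross_entropy(logits: Tensor, labels) -> Tensor:
    """Mean negative log softmax probability of the true class."""
    labels = np.asarray(labels, dtype=np.int64)
    num_classes = logits.shape[-1]
    if labels.size and (labels.min() < 0 or labels.max() >= num_classes):
        raise ValueError(f"labels outside [0, {num_classes})")
    log_probs = log_softmax(logits, axis=-1)
    onehot = np.zeros((labels.size, num_classes))
    onehot[np.arange(labels.size), labels] = 1.0
    picked = (log_probs * Tensor(onehot)).sum(axis=-1)
    return -picked.mean()


def prepare_arrays(items: list[LabeledImage], image_size: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Resize + normalize items into (N, 3, S, S) float and (N,) int labels."""
    xs = np.stack([normalize_standardize(resize_image(item.rgb(), image_size))
                   for item in items])
    ys = np.array([label_index(item.label) for item in items], dtype=np.int64)
    return xs, ys


def _epoch_losses(model: SwinTransformer, xs, ys, batch_size: int) -> float:
    model.eval()
    total, n = 0.0, 0
    for start in range(0, len(xs), batch_size):
        xb, yb = xs[start:start + batch_size], ys[start:start + batch_size]
        loss = cross_entropy(model(Tensor(xb)), yb)
        total += loss.item() * len(xb)
        n += len(xb)
    return total / max(n, 1)


def fit(model: SwinTransformer, split: DatasetSplit, config: TrainConfig,
        verbose: bool = False) -> tuple[SwinTransformer, TrainLog]:
    """Cosine-scheduled mini-batch SGD; returns the best-validation-loss model.

    Deterministic given ``config.seed`` (shuffling) and the model's own
    initialization seed.  A non-finite loss aborts with a diagnostic.
    """
    if not split.train or not split.val:
        raise ValueError("fit requires nonempty train and val partitions")
    x_train, y_train = prepare_arrays(split.train, config.image_size)
    x_val, y_val = prepare_arrays(split.val, config.image_size)
    rng = np.random.default_rng(config.seed)
    optimizer = SGD(model.parameters(), lr=config.lr0, momentum=config.momentum,
                    weight_decay=config.weight_decay)
    log = TrainLog()
    best_state, best_val = None, np.inf
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config.epochs, config.lr0)
        optimizer.lr = lr
        order = rng.permutation(len(x_train))
        model.train()
        epoch_loss, seen = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model(Tensor(x_train[idx]))
            loss = cross_entropy(logits, y_train[idx])
            value = loss.item()
            if not np.isfinite(value):
                raise TrainingDiverged(
                    f"non-finite loss {value} at epoch {epoch}; "
                    "reduce the learning rate or check the data")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += value * len(idx)
            seen += len(idx)
        val_loss = _epoch_losses(model, x_val, y_val, config.batch_size)
        log.append(epoch=epoch, lr=lr, train_loss=epoch_loss / seen,
                   val_loss=val_loss)
        if verbose:
            print(f"epoch {epoch:3d} lr {lr:.5f} "
                  f"train {epoch_loss / seen:.4f} val {val_loss:.4f}")
        if val_loss < best_val:
            best_val = val_loss
            best_state = copy.deepcopy(model.state_dict())
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, log


def evaluate_model(model: SwinTransformer, items: list[LabeledImage],
                   config: TrainConfig) -> MetricsReport:
    xs, ys = prepare_arrays(items, config.image_size)
    preds = model.predict(xs, batch_size=config.batch_size)
    return evaluate_predictions(ys, preds, model.config.num_classes)


def run_repeated(model_factories: dict, data_factory, n_runs: int,
                 base_seed: int = 0, train_config: TrainConfig | None = None,
                 ) -> dict[str, list[MetricsReport]]:
    """Repeated independent experiments with per-run seeds.

    Each run draws a fresh split (``data_factory(seed)``) and trains every
    model in ``model_factories`` (name -> factory(seed, placeholder-free))
    on that same split, so runs are paired across models.
    """
    if n_runs < 2:
        raise ValueError("need at least two runs for a paired comparison")
    train_config = train_config or desk_train_config()
    results: dict[str, list[MetricsReport]] = {name: [] for name in model_factories}
    for run in range(n_runs):
        seed = (base_seed + 1000 * run + 1) % (2 ** 31 - 1)
        split = data_factory(seed)
        for name, factory in model_factories.items():
            model = factory(seed)
            cfg = replace(train_config, seed=seed)
            try:
                model, _ = fit(model, split, cfg)
            except Exception as exc:
                raise RuntimeError(f"run {run} ({name}) failed") from exc
            results[name].append(evaluate_model(model, split.test, cfg))
    return results
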