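"""Training loop: cross-entropy objective, AdamW, early stopping, checkpointing.

Optimization follows the settings that work well for this architecture
family on small segmentation datasets: AdamW with learning rate 1e-4 and
weight decay 1e-2, batch size 4, and early stopping that tolerates 10
consecutive epochs without a strict improvement in validation loss. The
returned model always carries the weights of the best-validation epoch.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .model import SegmentationModel, images_to_batch
from .nn import AdamW, Tensor, no_grad
from .nn import autodiff as ad
from .preprocess import DatasetSplit
from .synthetic import Sample


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 4
    learning_rate: float = 1e-4
    weight_decay: float = 1e-2
    max_epochs: int = 30
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class TrainLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)
    best_epoch: int = 0          # 1-based
    stopped_epoch: int = 0


def cross_entropy_loss(logits, target) -> Tensor:
    """Mean per-pixel cross-entropy between class logits and a label mask.

    ``logits``: (B, C, H, W) tensor or array; ``target``: (B, H, W) integer
    labels. Softmax over the class axis; averaged over batch and pixels.
    """
    logits = logits if isinstance(logits, Tensor) else Tensor(logits)
    target = np.asarray(target)
    if logits.ndim == 3:
        logits = ad.reshape(logits, (1,) + logits.shape)
    if target.ndim == 2:
        target = target[None]
    if logits.shape[0] != target.shape[0] or logits.shape[2:] != target.shape[1:]:
        raise ValueError(f"logits {logits.shape} and target {target.shape} sizes differ")
    return ad.cross_entropy(logits, target)


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without strict improvement."""

    def __init__(self, patience: int = 10):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self.epochs_since_best = 0
        self.epoch = 0

    def update(self, epoch_val_loss: float) -> str:
        """Record one epoch's validation loss; return 'continue' or 'stop'."""
        self.epoch += 1
        if epoch_val_loss < self.best_loss:
            self.best_loss = epoch_val_loss
            self.best_epoch = self.epoch
            self.epochs_since_best = 0
        else:
            self.epochs_since_best += 1
        return "stop" if self.epochs_since_best >= self.patience else "continue"


def _epoch_pass(model, samples: list[Sample], batch_size: int,
                order: np.ndarray | None, optimizer: AdamW | None) -> float:
    """One pass over samples; trains if an optimizer is given. Returns mean loss."""
    idx = order if order is not None else np.arange(len(samples))
    total, count = 0.0, 0
    for start in range(0, len(idx), batch_size):
        chunk = idx[start:start + batch_size]
        images = images_to_batch([samples[i].image for i in chunk])
        target = np.stack([samples[i].mask for i in chunk]).astype(np.int64)
        if optimizer is None:
            with no_grad():
                loss = cross_entropy_loss(model(images), target)
        else:
            optimizer.zero_grad()
            loss = cross_entropy_loss(model(images), target)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss {loss.data!r}; aborting")
            loss.backward()
            optimizer.step()
        total += float(loss.data) * len(chunk)
        count += len(chunk)
    return total / count


def fit(model: SegmentationModel, split: DatasetSplit, samples: list[Sample],
        config: TrainConfig | None = None,
        verbose: bool = False) -> tuple[SegmentationModel, TrainLog]:
    """Train on ``split.train``, validate on ``split.val``.

    ``split`` holds integer indices into ``samples``. Mini-batch order is
    reshuffled each epoch from ``config.seed``, so runs are reproducible.
    The returned model holds the weights of the lowest-validation-loss epoch.
    """
    config = config or TrainConfig()
    if not split.train or not split.val:
        raise ValueError("both train and val splits must be non-empty")
    train_samples = [samples[i] for i in split.train]
    val_samples = [samples[i] for i in split.val]
    rng = np.random.default_rng(config.seed)
    optimizer = AdamW(model.parameters(), lr=config.learning_rate,
                      weight_decay=config.weight_decay)
    stopper = EarlyStopping(config.early_stop_patience)
    log = TrainLog()
    best_state = model.state_dict()
    for epoch in range(1, config.max_epochs + 1):
        t0 = time.perf_counter()
        order = rng.permutation(len(train_samples))
        tr_loss = _epoch_pass(model, train_samples, config.batch_size, order, optimizer)
        va_loss = _epoch_pass(model, val_samples, config.batch_size, None, None)
        log.train_loss.append(tr_loss)
        log.val_loss.append(va_loss)
        log.epoch_seconds.append(time.perf_counter() - t0)
        decision = stopper.update(va_loss)
        if stopper.best_epoch == epoch:
            best_state = model.state_dict()
        if verbose:
            print(f"epoch {epoch:3d}  train_loss {tr_loss:.4f}  "
                  f"val_loss {va_loss:.4f}  elapsed {log.epoch_seconds[-1]:.1f}s")
        log.stopped_epoch = epoch
        if decision == "stop":
            break
    log.best_epoch = stopper.best_epoch
    model.load_state_dict(best_state)
    return model, log
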