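"""Training protocol: one protein per batch, RMSprop, sparse categorical
cross-entropy, validation-based checkpoint selection.

Each optimization step consumes exactly one protein — all its windows for
the per-residue tasks, or its full contact map for the pair task — so the
effective batch size varies with protein length. A random fraction of the
training *proteins* (never individual windows, to avoid leakage between a
protein's own windows) is reserved for validation, and the checkpoint with
the highest validation accuracy is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import CMAPNetwork, SSRSANetwork
from .nn import RMSprop

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "ProteinSample",
    "split_train_validation",
    "train_model",
    "select_best_model",
]


@dataclass
class TrainConfig:
    epochs: int = 5
    validation_fraction: float = 0.10
    seed: int = 0
    learning_rate: float = 1e-3
    patience: int | None = None  # early stopping on the monitored metric
    clip_norm: float | None = None
    monitor: str = "accuracy"  # "accuracy" (per-residue tasks) or "loss" (contacts)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.monitor not in ("accuracy", "loss"):
            raise ValueError("monitor must be 'accuracy' or 'loss'")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass
class ProteinSample:
    """One protein's network inputs and per-residue (or per-pair) targets."""

    protein_id: str
    inputs: np.ndarray
    targets: np.ndarray


@dataclass
class TrainHistory:
    """Per-epoch records plus weight snapshots for best-model selection."""

    epochs: list[dict] = field(default_factory=list)
    checkpoints: list[list[np.ndarray]] = field(default_factory=list)
    validation_ids: list[str] = field(default_factory=list)


def split_train_validation(
    samples: list, fraction: float = 0.10, seed: int = 0
) -> tuple[list, list]:
    """Disjoint, exhaustive split; |validation| = round(fraction * n), min 1."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to split")
    n_val = max(1, round(fraction * len(samples)))
    if n_val >= len(samples):
        n_val = len(samples) - 1
    order = np.random.default_rng(seed).permutation(len(samples))
    val_idx = set(order[:n_val].tolist())
    train = [s for i, s in enumerate(samples) if i not in val_idx]
    val = [s for i, s in enumerate(samples) if i in val_idx]
    return train, val


def _accuracy(model, samples: list[ProteinSample]) -> float:
    correct = total = 0
    for s in samples:
        proba = model.predict_proba(s.inputs)
        pred = proba.argmax(axis=-1)
        correct += int((pred == s.targets).sum())
        total += s.targets.size
    return correct / max(total, 1)


def train_model(
    model, data: list[ProteinSample], cfg: TrainConfig
) -> tuple[object, TrainHistory]:
    """Run the training loop and record per-epoch history.

    Returns the model (weights as of the last completed epoch) and the
    history; restore the best epoch with :func:`select_best_model` +
    ``model.set_state``.
    """
    if not data:
        raise ValueError("no training data")
    if not isinstance(model, (SSRSANetwork, CMAPNetwork)):
        raise TypeError("model must be an SSRSANetwork or CMAPNetwork")
    n_classes = model.hp.n_classes
    for s in data:
        if s.targets.max() >= n_classes or s.targets.min() < 0:
            raise ValueError(
                f"targets of {s.protein_id} outside 0..{n_classes - 1}"
            )
    train, val = split_train_validation(data, cfg.validation_fraction, cfg.seed)
    optimizer = RMSprop(model.parameters(), lr=cfg.learning_rate, clip_norm=cfg.clip_norm)
    rng = np.random.default_rng(cfg.seed + 1)
    history = TrainHistory(validation_ids=[s.protein_id for s in val])
    best_score, since_best = -np.inf, 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train))
        losses = []
        for idx in order:
            s = train[idx]
            optimizer.zero_grad()
            loss = model.loss(s.inputs, s.targets, train=True)
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        val_losses = [
            float(model.loss(s.inputs, s.targets, train=False).data) for s in val
        ]
        val_acc = _accuracy(model, val)
        history.epochs.append(
            {
                "epoch": epoch + 1,
                "train_loss": float(np.mean(losses)),
                "val_loss": float(np.mean(val_losses)),
                "val_accuracy": val_acc,
                "steps": len(train),
            }
        )
        history.checkpoints.append(model.get_state())
        score = val_acc if cfg.monitor == "accuracy" else -float(np.mean(val_losses))
        if score > best_score:
            best_score, since_best = score, 0
        else:
            since_best += 1
            if cfg.patience is not None and since_best >= cfg.patience:
                break
    return model, history


def select_best_model(history: TrainHistory, monitor: str = "accuracy") -> int:
    """Index of the best checkpoint: highest validation accuracy (default)
    or lowest validation loss; earliest epoch wins ties."""
    if not history.epochs:
        raise ValueError("empty training history")
    if monitor == "accuracy":
        scores = [e["val_accuracy"] for e in history.epochs]
    elif monitor == "loss":
        scores = [-e["val_loss"] for e in history.epochs]
    else:
        raise ValueError("monitor must be 'accuracy' or 'loss'")
    return int(np.argmax(scores))  # argmax returns the first maximum
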