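"""Scikit-learn style estimators over the alignment networks.

Because every sample is a whole protein of its own length, ``X`` is a list
of encoded alignments (or raw integer matrices) and ``y`` a list of
per-residue label arrays (or per-pair contact maps); ``predict`` returns a
list with one array per protein. Estimators follow the sklearn parameter
contract (``get_params``/``set_params``, fitted attributes with trailing
underscores) so they compose with sklearn model-selection tooling that
accepts list-like X.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .models import (
    CMAPNetwork,
    HyperParams,
    SSRSANetwork,
    build_cmap_model,
    build_ss_rsa_model,
)
from .msa import EncodedMSA, extract_windows
from .training import ProteinSample, TrainConfig, select_best_model, train_model

__all__ = ["SecondaryStructureNet", "ContactMapNet"]


def _msa_values(x, depth_cap: int) -> np.ndarray:
    values = x.values if isinstance(x, EncodedMSA) else np.asarray(x)
    if values.shape[0] != depth_cap:
        raise ValueError(
            f"alignment depth {values.shape[0]} != estimator depth_cap {depth_cap}"
        )
    return values


class SecondaryStructureNet(BaseEstimator):
    """Per-residue classifier (secondary structure or solvent accessibility).

    Slides a 31-column window over the encoded alignment and classifies the
    central residue. ``classes_`` is inferred from ``y``, so the same
    estimator serves the 3-class SS task and the 4-/2-class RSA tasks.

    Parameters mirror the architecture hyperparameters; ``pool_window`` and
    ``filters`` default to ``embedding_dim``.
    """

    def __init__(
        self,
        embedding_dim: int = 10,
        depth_cap: int = 500,
        window: int = 31,
        pool_window: int | None = None,
        filters: int | None = None,
        n_column_stages: int = 1,
        lstm_units: int = 350,
        lstm_layers: int = 2,
        dense_units: tuple[int, ...] = (200, 200),
        dropout: float = 0.4,
        epochs: int = 5,
        learning_rate: float = 1e-3,
        validation_fraction: float = 0.1,
        patience: int | None = None,
        random_state: int = 0,
    ):
        self.embedding_dim = embedding_dim
        self.depth_cap = depth_cap
        self.window = window
        self.pool_window = pool_window
        self.filters = filters
        self.n_column_stages = n_column_stages
        self.lstm_units = lstm_units
        self.lstm_layers = lstm_layers
        self.dense_units = dense_units
        self.dropout = dropout
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.random_state = random_state

    # -- internals --------------------------------------------------------

    def _windows(self, x) -> np.ndarray:
        values = _msa_values(x, self.depth_cap)
        msa = x if isinstance(x, EncodedMSA) else EncodedMSA(values, values.shape[0])
        return np.stack([w.values for w in extract_windows(msa, self.window)])

    def _hyperparams(self, n_classes: int) -> HyperParams:
        return HyperParams(
            embedding_dim=self.embedding_dim,
            depth_cap=self.depth_cap,
            window=self.window,
            pool_window=self.pool_window,
            filters=self.filters,
            n_column_stages=self.n_column_stages,
            lstm_units=self.lstm_units,
            lstm_layers=self.lstm_layers,
            dense_units=tuple(self.dense_units),
            dropout=self.dropout,
            n_classes=n_classes,
        )

    # -- sklearn surface --------------------------------------------------

    def fit(self, X, y):
        """X: list of encoded alignments; y: list of per-residue labels."""
        if len(X) != len(y):
            raise ValueError("X and y must have one entry per protein")
        self.classes_ = np.unique(np.concatenate([np.asarray(t) for t in y]))
        class_index = {c: i for i, c in enumerate(self.classes_)}
        samples = []
        for k, (x, t) in enumerate(zip(X, y)):
            targets = np.array([class_index[c] for c in np.asarray(t)])
            windows = self._windows(x)
            if len(targets) != windows.shape[0]:
                raise ValueError(f"protein {k}: {len(targets)} labels for {windows.shape[0]} residues")
            samples.append(ProteinSample(str(k), windows, targets))
        hp = self._hyperparams(len(self.classes_))
        model = build_ss_rsa_model(hp, seed=self.random_state)
        cfg = TrainConfig(
            epochs=self.epochs,
            validation_fraction=self.validation_fraction,
            seed=self.random_state,
            learning_rate=self.learning_rate,
            patience=self.patience,
        )
        model, history = train_model(model, samples, cfg)
        best = select_best_model(history)
        model.set_state(history.checkpoints[best])
        self.model_ = model
        self.history_ = history
        self.best_epoch_ = best + 1
        return self

    def predict_proba(self, X) -> list[np.ndarray]:
        self._check_fitted()
        return [self.model_.predict_proba(self._windows(x)) for x in X]

    def predict(self, X) -> list[np.ndarray]:
        self._check_fitted()
        return [self.classes_[p.argmax(axis=-1)] for p in self.predict_proba(X)]

    def score(self, X, y) -> float:
        """Mean per-protein accuracy (each protein weighted equally)."""
        preds = self.predict(X)
        accs = [
            float(np.mean(p == np.asarray(t))) for p, t in zip(preds, y)
        ]
        return float(np.mean(accs))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")

    @property
    def embedding_matrix_(self) -> np.ndarray:
        self._check_fitted()
        return self.model_.embed.weight.data


class ContactMapNet(BaseEstimator):
    """Residue-residue contact predictor over whole alignments.

    ``fit`` consumes full encoded alignments and L x L binary contact maps;
    ``predict_proba`` returns per-protein L x L contact-probability maps
    (symmetrize downstream before ranking pairs).
    """

    def __init__(
        self,
        embedding_dim: int = 10,
        depth_cap: int = 100,
        pool_window: int | None = None,
        filters: int | None = None,
        n_column_stages: int = 2,
        trunk_depth: int = 6,
        trunk_kernel: int = 3,
        trunk_filters: int = 10,
        epochs: int = 30,
        learning_rate: float = 1e-3,
        validation_fraction: float = 0.1,
        patience: int | None = 10,
        clip_norm: float | None = None,
        random_state: int = 0,
    ):
        self.embedding_dim = embedding_dim
        self.depth_cap = depth_cap
        self.pool_window = pool_window
        self.filters = filters
        self.n_column_stages = n_column_stages
        self.trunk_depth = trunk_depth
        self.trunk_kernel = trunk_kernel
        self.trunk_filters = trunk_filters
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.clip_norm = clip_norm
        self.random_state = random_state

    def _hyperparams(self) -> HyperParams:
        return HyperParams(
            embedding_dim=self.embedding_dim,
            depth_cap=self.depth_cap,
            pool_window=self.pool_window,
            filters=self.filters,
            n_column_stages=self.n_column_stages,
            cmap_trunk_depth=self.trunk_depth,
            cmap_kernel=self.trunk_kernel,
            cmap_filters=self.trunk_filters,
            n_classes=2,
        )

    def fit(self, X, y):
        """X: list of encoded alignments; y: list of L x L binary maps."""
        if len(X) != len(y):
            raise ValueError("X and y must have one entry per protein")
        samples = []
        for k, (x, cmap) in enumerate(zip(X, y)):
            values = _msa_values(x, self.depth_cap)
            target = np.asarray(getattr(cmap, "values", cmap)).astype(np.int64)
            if target.shape != (values.shape[1], values.shape[1]):
                raise ValueError(f"protein {k}: contact map shape mismatch")
            samples.append(ProteinSample(str(k), values, target))
        model = build_cmap_model(self._hyperparams(), seed=self.random_state)
        # contact models are checkpointed on lowest validation error; plain
        # accuracy is uninformative under the heavy contact/non-contact
        # class imbalance
        cfg = TrainConfig(
            epochs=self.epochs,
            validation_fraction=self.validation_fraction,
            seed=self.random_state,
            learning_rate=self.learning_rate,
            patience=self.patience,
            clip_norm=self.clip_norm,
            monitor="loss",
        )
        model, history = train_model(model, samples, cfg)
        best = select_best_model(history, monitor="loss")
        model.set_state(history.checkpoints[best])
        self.model_ = model
        self.history_ = history
        self.best_epoch_ = best + 1
        return self

    def predict_proba(self, X) -> list[np.ndarray]:
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")
        return [
            self.model_.predict_proba(_msa_values(x, self.depth_cap)) for x in X
        ]
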