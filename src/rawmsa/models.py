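"""Network architectures operating directly on integer-coded alignments.

Two architectures share a common front end (embedding layer + column-wise
convolution/pooling stages that never mix information across residue
positions):

* the per-residue network (``SSRSANetwork``) slides a 31-column window over
  the alignment and classifies the central residue (secondary structure in
  3 classes, or solvent accessibility in 4 or 2 classes) with stacked
  bidirectional LSTMs and fully connected softmax heads;
* the pair network (``CMAPNetwork``) consumes the whole alignment at once,
  lifts the per-position hidden tensor H (L x F x S) to an L x L pair
  tensor via an elementwise outer product OP[i,j] = H[i] * H[j], and
  refines it with a stack of square 2D convolutions into an L x L x 2
  contact/non-contact softmax map.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .msa import DEFAULT_VOCABULARY, ResidueVocabulary
from .nn import (
    BatchNorm,
    BiLSTM,
    ColumnConvPool,
    Conv2dSame,
    Dense,
    Dropout,
    Embedding,
    Module,
    Tensor,
    softmax,
    sparse_softmax_cross_entropy,
)

__all__ = [
    "HyperParams",
    "SSRSANetwork",
    "CMAPNetwork",
    "build_ss_rsa_model",
    "build_cmap_model",
    "outer_product_expand",
    "embedding_similarity",
    "save_model",
    "load_model",
]


@dataclass
class HyperParams:
    """Architecture hyperparameters; one dataclass serves both networks.

    `pool_window` and `filters` default to the embedding size E when left
    as None, matching the convention that the column convolution uses as
    many filters as embedding dimensions and a 1 x E window.
    """

    embedding_dim: int = 10          # E, typically 10-30
    depth_cap: int = 500             # Y, max alignment rows
    window: int = 31                 # sliding-window width (per-residue tasks)
    pool_window: int | None = None   # W; None -> embedding_dim
    filters: int | None = None       # column-conv filters; None -> embedding_dim
    n_column_stages: int = 1         # 1 for SS-RSA, up to 6 for contact maps
    lstm_units: int = 350            # per direction
    lstm_layers: int = 2
    dense_units: tuple[int, ...] = (200, 200)
    dropout: float = 0.4
    cmap_trunk_depth: int = 6        # 6-20 square-conv layers
    cmap_kernel: int = 3             # 3, 5 or 10
    cmap_filters: int = 10           # 10-50
    n_classes: int = 3               # 3 (SS), 4 or 2 (RSA), 2 (contacts)

    def __post_init__(self):
        if self.pool_window is None:
            self.pool_window = self.embedding_dim
        if self.filters is None:
            self.filters = self.embedding_dim
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if self.depth_cap < 1:
            raise ValueError("depth_cap must be >= 1")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd integer")
        for name in (
            "pool_window",
            "filters",
            "n_column_stages",
            "lstm_units",
            "lstm_layers",
            "cmap_trunk_depth",
            "cmap_kernel",
            "cmap_filters",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_classes not in (2, 3, 4):
            raise ValueError("n_classes must be 2, 3 or 4")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HyperParams":
        d = dict(d)
        if "dense_units" in d and d["dense_units"] is not None:
            d["dense_units"] = tuple(d["dense_units"])
        return cls(**d)


def outer_product_expand(hidden) -> np.ndarray | Tensor:
    """Lift per-position features H (L x F x S) to pairs: OP[i,j,f,s] =
    H[i,f,s] * H[j,f,s], flattened to (L, L, F*S).

    Works on plain arrays and on autograd tensors (used inside the pair
    network, where the gradient flows through the product).
    """
    if isinstance(hidden, Tensor):
        length = hidden.shape[0]
        flat = hidden.reshape(length, -1)
        m = flat.shape[1]
        return flat.reshape(length, 1, m) * flat.reshape(1, length, m)
    hidden = np.asarray(hidden)
    if hidden.size == 0:
        raise ValueError("hidden tensor must be non-empty")
    length = hidden.shape[0]
    flat = hidden.reshape(length, -1)
    return flat[:, None, :] * flat[None, :, :]


def _column_front_end(hp: HyperParams, rng: np.random.Generator) -> list[ColumnConvPool]:
    stages = []
    in_ch = hp.embedding_dim
    for _ in range(hp.n_column_stages):
        stages.append(
            ColumnConvPool(in_ch, hp.filters, kernel=hp.pool_window, pool=hp.pool_window, rng=rng)
        )
        in_ch = hp.filters
    return stages


class SSRSANetwork(Module):
    """Window classifier: embedding -> column conv/pool -> BiLSTM stack ->
    fully connected softmax head for the central residue."""

    def __init__(self, hp: HyperParams, seed: int = 0):
        self.hp = hp
        self.rng = np.random.default_rng(seed)
        rng = self.rng
        self.embed = Embedding(DEFAULT_VOCABULARY.size + 1, hp.embedding_dim, rng)
        self.stages = _column_front_end(hp, rng)
        pooled = hp.depth_cap
        for _ in range(hp.n_column_stages):
            pooled //= hp.pool_window
        if pooled < 1:
            raise ValueError(
                "column stages pool the alignment depth away entirely; "
                "reduce n_column_stages or pool_window"
            )
        per_column = pooled * hp.filters
        self.lstms = []
        in_size = per_column
        for layer in range(hp.lstm_layers):
            last = layer == hp.lstm_layers - 1
            self.lstms.append(
                BiLSTM(in_size, hp.lstm_units, rng, return_sequences=not last)
            )
            in_size = 2 * hp.lstm_units
        self.dropouts = [Dropout(hp.dropout, rng) for _ in range(hp.lstm_layers + len(hp.dense_units))]
        self.dense = []
        for units in hp.dense_units:
            self.dense.append(Dense(in_size, units, rng, activation="relu"))
            in_size = units
        self.head = Dense(in_size, hp.n_classes, rng)

    def forward(self, windows: np.ndarray, train: bool = False) -> Tensor:
        """`windows`: integer array (batch, Y, width) -> logits (batch, C)."""
        windows = np.asarray(windows)
        x = self.embed(np.swapaxes(windows, 1, 2))  # (B, width, Y, E)
        for stage in self.stages:
            x = stage(x)
        b, w = x.shape[0], x.shape[1]
        x = x.reshape(b, w, -1)
        drop = iter(self.dropouts)
        for lstm in self.lstms:
            x = lstm(x)
            x = next(drop)(x, train=train)
        for layer in self.dense:
            x = layer(x)
            x = next(drop)(x, train=train)
        return self.head(x)

    def loss(self, windows: np.ndarray, targets: np.ndarray, train: bool = True) -> Tensor:
        return sparse_softmax_cross_entropy(self.forward(windows, train=train), targets)

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        return softmax(self.forward(windows, train=False).data)

    # -- weight snapshots -------------------------------------------------

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p.data = s.copy()


class CMAPNetwork(Module):
    """Pair network: embedding -> column conv/pool stages -> outer-product
    expansion -> square-conv trunk with batch normalization -> 2-class
    softmax per residue pair. Accepts any master length without rebuild."""

    def __init__(self, hp: HyperParams, seed: int = 0):
        self.hp = hp
        self.rng = np.random.default_rng(seed)
        rng = self.rng
        self.embed = Embedding(DEFAULT_VOCABULARY.size + 1, hp.embedding_dim, rng)
        self.stages = _column_front_end(hp, rng)
        pooled = hp.depth_cap
        for _ in range(hp.n_column_stages):
            pooled //= hp.pool_window
        if pooled < 1:
            raise ValueError(
                "column stages pool the alignment depth away entirely; "
                "reduce n_column_stages or pool_window"
            )
        pair_channels = pooled * hp.filters
        self.trunk: list[Conv2dSame] = []
        self.norms: list[BatchNorm] = []
        in_ch = pair_channels
        for _ in range(hp.cmap_trunk_depth - 1):
            self.trunk.append(Conv2dSame(in_ch, hp.cmap_filters, hp.cmap_kernel, rng))
            self.norms.append(BatchNorm(hp.cmap_filters))
            in_ch = hp.cmap_filters
        self.final = Conv2dSame(in_ch, 2, hp.cmap_kernel, rng)

    def front_end(self, msa_values: np.ndarray, train: bool = False) -> Tensor:
        """Per-position hidden tensor H with shape (L, pooled depth, filters).

        Output at position i depends only on alignment column i.
        """
        msa_values = np.asarray(msa_values)
        x = self.embed(msa_values.T[None, :, :])  # (1, L, Y, E)
        for stage in self.stages:
            x = stage(x)
        return x.reshape(x.shape[1], x.shape[2], x.shape[3])

    def forward(self, msa_values: np.ndarray, train: bool = False) -> Tensor:
        hidden = self.front_end(msa_values, train=train)
        length = hidden.shape[0]
        pairs = outer_product_expand(hidden)  # (L, L, F*S)
        x = pairs.reshape(1, length, length, -1)
        for conv, norm in zip(self.trunk, self.norms):
            x = conv(x).relu()
            x = norm(x, train=train)
        logits = self.final(x)  # (1, L, L, 2)
        return logits.reshape(length, length, 2)

    def loss(self, msa_values: np.ndarray, contact_map: np.ndarray, train: bool = True) -> Tensor:
        logits = self.forward(msa_values, train=train)
        return sparse_softmax_cross_entropy(logits, np.asarray(contact_map))

    def predict_proba(self, msa_values: np.ndarray) -> np.ndarray:
        """(L, L) probability of the contact class (not yet symmetrized)."""
        logits = self.forward(msa_values, train=False)
        return softmax(logits.data)[:, :, 1]

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p.data = s.copy()


def build_ss_rsa_model(hp: HyperParams, seed: int = 0) -> SSRSANetwork:
    """Assemble the per-residue classifier (n_classes must be 3, 4 or 2)."""
    return SSRSANetwork(hp, seed=seed)


def build_cmap_model(hp: HyperParams, seed: int = 0) -> CMAPNetwork:
    """Assemble the contact-map network."""
    return CMAPNetwork(hp, seed=seed)


def embedding_similarity(
    embedding_matrix: np.ndarray,
    query: str,
    k: int = 5,
    vocab: ResidueVocabulary = DEFAULT_VOCABULARY,
) -> list[tuple[str, float]]:
    """Rank vocabulary symbols by cosine similarity to the query's vector.

    Accepts either the raw (26 x E) layer weight (row 0 = padding) or a
    (25 x E) matrix of symbol rows. The query itself is excluded.
    """
    matrix = np.asarray(embedding_matrix, dtype=float)
    if matrix.shape[0] == vocab.size + 1:
        row = lambda idx: matrix[idx]  # noqa: E731
    elif matrix.shape[0] == vocab.size:
        row = lambda idx: matrix[idx - 1]  # noqa: E731
    else:
        raise ValueError("embedding matrix must have one row per symbol")
    query = query.upper()
    if query not in vocab.symbol_to_index:
        raise KeyError(f"unknown residue code {query!r}")
    if k >= vocab.size:
        raise ValueError("k must be smaller than the vocabulary size")
    qv = row(vocab.symbol_to_index[query])
    sims = []
    for symbol, idx in vocab.symbol_to_index.items():
        if symbol == query:
            continue
        v = row(idx)
        denom = np.linalg.norm(qv) * np.linalg.norm(v)
        sims.append((symbol, float(qv @ v / denom) if denom > 0 else 0.0))
    sims.sort(key=lambda t: -t[1])
    return sims[:k]


def save_model(model, path) -> None:
    """Save weights plus architecture metadata to an .npz checkpoint."""
    meta = {
        "task_class": type(model).__name__,
        "hyperparams": model.hp.to_dict(),
    }
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    if isinstance(model, CMAPNetwork):
        for i, norm in enumerate(model.norms):
            arrays[f"running_mean_{i}"] = norm.running_mean
            arrays[f"running_var_{i}"] = norm.running_var
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path):
    """Rebuild a network from a checkpoint written by :func:`save_model`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        hp = HyperParams.from_dict(meta["hyperparams"])
        cls = {"SSRSANetwork": SSRSANetwork, "CMAPNetwork": CMAPNetwork}[meta["task_class"]]
        model = cls(hp)
        state = [data[f"param_{i}"] for i in range(len(model.parameters()))]
        model.set_state(state)
        if isinstance(model, CMAPNetwork):
            for i, norm in enumerate(model.norms):
                norm.running_mean = data[f"running_mean_{i}"].copy()
                norm.running_var = data[f"running_var_{i}"].copy()
    return model
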