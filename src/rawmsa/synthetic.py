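"""Desk-scale synthetic data with the statistical structure the networks
must learn.

Two generative models are provided:

* a hidden-Markov secondary-structure generator: a per-column class path
  over {H, E, C} drawn from a sticky Markov chain, with every sequence in
  the alignment emitting class-enriched residues at each column (helix
  formers for H, sheet formers for E, turn/loop residues for C) — so the
  column composition carries the label, much as real structural classes
  skew amino-acid propensities;
* a planted-covariation contact generator: a sparse set of long-range
  column pairs that co-emit complementary (charge-pair) residues, the
  coevolution-like signal contact predictors exploit, against an otherwise
  uniform background.

Both are pure functions of their configuration and seed. Neither models
phylogenetic correlation between sequences or realistic indel processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import ContactMap, StructureLabels, long_range_pairs
from .msa import GAP, RawAlignment

__all__ = [
    "SyntheticConfig",
    "generate_ss_msa",
    "generate_contact_msa",
    "generate_toy_structure",
    "SS_EMISSION_SETS",
    "RSA_EMISSION_SETS",
    "COMPLEMENTARY_PAIRS",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"

# Class-enriched residue sets, loosely following helix/sheet/coil propensities.
SS_EMISSION_SETS = {"H": "AELM", "E": "VIYW", "C": "GPNS"}
# Burial-class sets: buried cores are hydrophobic, exposed surfaces polar/charged.
RSA_EMISSION_SETS = {
    "Buried": "LIVF",
    "PartiallyBuried": "AMCW",
    "PartiallyAccessible": "TSYH",
    "Accessible": "KREQ",
}
# Representative RSA fractions, one per class, consistent with the
# [0,0.04], (0.04,0.25], (0.25,0.5], (0.5,1] thresholds.
_RSA_CLASS_VALUES = {
    "Buried": 0.02,
    "PartiallyBuried": 0.15,
    "PartiallyAccessible": 0.38,
    "Accessible": 0.75,
}
# Charge-complementary residue pairs co-emitted at planted contact columns.
COMPLEMENTARY_PAIRS = [("K", "E"), ("R", "D"), ("E", "K"), ("D", "R")]


def _sticky_transition(n: int, stay: float) -> np.ndarray:
    off = (1.0 - stay) / (n - 1)
    return np.full((n, n), off) + np.eye(n) * (stay - off)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generators.

    `ss_transition` rows must sum to 1; the default is a symmetric sticky
    chain (stay probability 0.9) whose stationary distribution is uniform.
    `emission_strength` is the probability mass placed on the class-specific
    residue subset; the rest is uniform over all 20 residues.
    """

    L: int = 60
    N: int = 30
    n_proteins: int = 50
    ss_transition: np.ndarray = field(default_factory=lambda: _sticky_transition(3, 0.9))
    emission_strength: float = 0.7
    gap_rate: float = 0.05
    contact_density: float = 0.05
    coupling_strength: float = 0.8
    seed: int = 0

    def __post_init__(self):
        self.ss_transition = np.asarray(self.ss_transition, dtype=float)
        if self.ss_transition.shape != (3, 3) or not np.allclose(
            self.ss_transition.sum(axis=1), 1.0
        ):
            raise ValueError("ss_transition must be 3x3 with rows summing to 1")
        for name in ("emission_strength", "gap_rate", "contact_density", "coupling_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.L < 1 or self.N < 1 or self.n_proteins < 1:
            raise ValueError("L, N and n_proteins must be positive")


def _markov_path(rng, transition: np.ndarray, states: list[str], length: int) -> list[str]:
    n = len(states)
    # start from the stationary distribution of the chain
    evals, evecs = np.linalg.eig(transition.T)
    stat = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
    stat = np.abs(stat) / np.abs(stat).sum()
    path = [int(rng.choice(n, p=stat))]
    for _ in range(length - 1):
        path.append(int(rng.choice(n, p=transition[path[-1]])))
    return [states[i] for i in path]


def _emit_column(rng, enriched: str, strength: float, n: int) -> list[str]:
    out = []
    for _ in range(n):
        if rng.random() < strength:
            out.append(enriched[rng.integers(len(enriched))])
        else:
            out.append(_AA[rng.integers(20)])
    return out


def generate_ss_msa(
    cfg: SyntheticConfig, signal: str = "ss"
) -> tuple[RawAlignment, StructureLabels]:
    """One synthetic alignment whose columns encode structural classes.

    ``signal='ss'`` emits residues from the secondary-structure class sets;
    ``signal='rsa'`` emits from the burial-class sets instead, so solvent
    accessibility becomes the learnable signal. Both label families are
    always returned (the one not driving the emissions follows its own
    independent chain). The master row receives no gaps, so labels stay
    aligned with master positions; other rows are hit by gaps at
    ``gap_rate``.
    """
    if signal not in ("ss", "rsa"):
        raise ValueError("signal must be 'ss' or 'rsa'")
    rng = np.random.default_rng(cfg.seed)
    ss_path = _markov_path(rng, cfg.ss_transition, ["H", "E", "C"], cfg.L)
    rsa_transition = _sticky_transition(4, 0.9)
    rsa_path = _markov_path(rng, rsa_transition, list(RSA_EMISSION_SETS), cfg.L)

    columns = []
    for i in range(cfg.L):
        enriched = (
            SS_EMISSION_SETS[ss_path[i]]
            if signal == "ss"
            else RSA_EMISSION_SETS[rsa_path[i]]
        )
        col = _emit_column(rng, enriched, cfg.emission_strength, cfg.N)
        for r in range(1, cfg.N):
            if rng.random() < cfg.gap_rate:
                col[r] = GAP
        columns.append(col)
    sequences = ["".join(columns[i][r] for i in range(cfg.L)) for r in range(cfg.N)]
    rsa = np.array([_RSA_CLASS_VALUES[c] for c in rsa_path])
    labels = StructureLabels(
        ss3=np.array(ss_path),
        rsa=rsa,
        rsa4=np.array(rsa_path),
        rsa2=np.array(["Buried" if v <= 0.25 else "Accessible" for v in rsa]),
    )
    return RawAlignment(sequences), labels


def generate_contact_msa(cfg: SyntheticConfig) -> tuple[RawAlignment, ContactMap]:
    """Alignment with planted covarying long-range column pairs.

    Planted pairs are drawn from the long-range set (separation over 23) at
    ``contact_density``; within each sequence, each planted pair co-emits a
    complementary charge pair with probability ``coupling_strength``. All
    remaining cells are independent uniform residues. The truth map is the
    planted pair set (symmetric, diagonal 1 by the zero-self-distance
    convention, no other long-range contacts).
    """
    if cfg.L < 25:
        raise ValueError("L must be >= 25 so long-range pairs exist")
    rng = np.random.default_rng(cfg.seed)
    eligible = sorted(long_range_pairs(cfg.L))
    n_planted = max(1, round(cfg.contact_density * len(eligible)))
    chosen = [eligible[i] for i in rng.choice(len(eligible), size=n_planted, replace=False)]

    grid = np.array([[_AA[rng.integers(20)] for _ in range(cfg.L)] for _ in range(cfg.N)])
    # couple pairs row by row in random order; a cell already claimed by an
    # earlier pair in that row keeps its coupling (no overwriting), so every
    # planted pair retains covariation even when pairs share a column
    for r in range(cfg.N):
        claimed = np.zeros(cfg.L, dtype=bool)
        for k in rng.permutation(len(chosen)):
            i, j = chosen[k][0] - 1, chosen[k][1] - 1
            if claimed[i] or claimed[j]:
                continue
            if rng.random() < cfg.coupling_strength:
                a, b = COMPLEMENTARY_PAIRS[rng.integers(len(COMPLEMENTARY_PAIRS))]
                grid[r, i], grid[r, j] = a, b
                claimed[i] = claimed[j] = True
    sequences = ["".join(row) for row in grid]

    values = np.eye(cfg.L, dtype=np.int8)
    for i1, j1 in chosen:
        values[i1 - 1, j1 - 1] = values[j1 - 1, i1 - 1] = 1
    return RawAlignment(sequences), ContactMap(values=values)


def generate_toy_structure(
    L: int, seed: int = 0
) -> tuple[np.ndarray, ContactMap]:
    """A straight 3.8 Å-spaced chain under a random rigid motion, with its
    analytically known contact map (|i - j| <= 2 at the 8 Å cutoff, since
    2 * 3.8 = 7.6 < 8 < 3 * 3.8).

    The seed only picks the rigid rotation/translation, which leaves the
    distance matrix — hence the contact map — unchanged.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    coords = np.zeros((L, 3))
    coords[:, 0] = 3.8 * np.arange(L)
    rng = np.random.default_rng(seed)
    # random rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    coords = coords @ q.T + rng.normal(scale=10.0, size=3)
    idx = np.arange(L)
    values = (np.abs(idx[:, None] - idx[None, :]) <= 2).astype(np.int8)
    return coords, ContactMap(values=values)
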