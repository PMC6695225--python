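"""Reading, integer-encoding and windowing of multiple sequence alignments.

An alignment is consumed as-is (flat aligned FASTA, or A3M flattened by
deleting lowercase insertion states): no profile or PSSM is ever computed.
Each residue symbol maps to an integer in 1..25 (20 standard residues in
alphabetical one-letter order, then B, U, Z, X and the gap ``-``); 0 is
reserved for zero-padding so real residues can never collide with padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "ResidueVocabulary",
    "RawAlignment",
    "EncodedMSA",
    "MSAWindow",
    "DEFAULT_VOCABULARY",
    "read_alignment",
    "flatten_a3m",
    "encode_msa",
    "reorder_sequences",
    "extract_windows",
]

_STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


@dataclass(frozen=True)
class ResidueVocabulary:
    """Bijection from the 25 alignment symbols onto {1..25}.

    Letters outside the vocabulary (J, O, *, ...) collapse to the ambiguity
    symbol X. Index 0 is never assigned: it is reserved for padding.
    """

    symbol_to_index: dict[str, int] = field(
        default_factory=lambda: {
            **{aa: i + 1 for i, aa in enumerate(_STANDARD_RESIDUES)},
            "B": 21,
            "U": 22,
            "Z": 23,
            "X": 24,
            GAP: 25,
        }
    )
    unknown_symbol: str = "X"

    def __post_init__(self):
        indices = sorted(self.symbol_to_index.values())
        if indices != list(range(1, len(self.symbol_to_index) + 1)):
            raise ValueError("vocabulary indices must be a bijection onto 1..n")

    @property
    def size(self) -> int:
        return len(self.symbol_to_index)

    @property
    def gap_index(self) -> int:
        return self.symbol_to_index[GAP]

    def index(self, symbol: str) -> int:
        symbol = symbol.upper()
        if symbol not in self.symbol_to_index:
            symbol = self.unknown_symbol
        return self.symbol_to_index[symbol]

    def encode(self, sequence: str) -> np.ndarray:
        return np.array([self.index(s) for s in sequence], dtype=np.int64)

    def decode(self, indices: np.ndarray) -> str:
        inverse = {i: s for s, i in self.symbol_to_index.items()}
        return "".join(inverse[int(i)] for i in indices)


DEFAULT_VOCABULARY = ResidueVocabulary()


@dataclass
class RawAlignment:
    """Equal-length aligned sequences; the master (target) is row 0.

    Columns where the master has a gap are removed at construction, so the
    width always equals the master length L.
    """

    sequences: list[str]
    master_index: int = 0

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("ragged alignment: sequences have unequal lengths")
        master = self.sequences[self.master_index]
        if GAP in master:
            keep = [i for i, c in enumerate(master) if c != GAP]
            self.sequences = [
                "".join(s[i] for i in keep) for s in self.sequences
            ]

    @property
    def master(self) -> str:
        return self.sequences[self.master_index]

    @property
    def length(self) -> int:
        return len(self.master)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)


@dataclass
class EncodedMSA:
    """Integer alignment matrix of shape (depth_cap Y, master length L).

    Rows beyond min(N, Y) are all zero (padding); real rows never contain 0.
    """

    values: np.ndarray
    n_sequences: int

    @property
    def depth(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]


@dataclass
class MSAWindow:
    """A (Y, width) slice of an encoded MSA centred on one master residue."""

    values: np.ndarray
    center: int


def _validate_symbols(seq: str, a3m: bool) -> None:
    for ch in seq:
        if ch.isalpha() or ch in (GAP, "*"):
            continue
        if ch == "." and a3m:
            continue
        raise ValueError(f"illegal character {ch!r} in alignment")


def read_alignment(path, format: str = "fasta") -> RawAlignment:
    """Read an alignment file; the first record is the master sequence.

    ``format='a3m'`` removes lowercase insertion states before aligning
    widths (see :func:`flatten_a3m`); flat FASTA is parsed
    case-insensitively and must already be rectangular.
    """
    if format not in ("fasta", "a3m"):
        raise ValueError(f"unknown alignment format {format!r}")
    records = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError("no sequences")
    if format == "a3m":
        return flatten_a3m(records)
    for seq in records:
        _validate_symbols(seq, a3m=False)
    return RawAlignment([s.upper() for s in records])


def flatten_a3m(records: list[str]) -> RawAlignment:
    """Delete lowercase insertion states so every record matches the master.

    The master (first record) must itself be insertion-free; any record
    whose flattened length differs from the master's is an error.
    """
    if not records:
        raise ValueError("no sequences")
    for seq in records:
        _validate_symbols(seq, a3m=True)
    flattened = ["".join(c for c in seq if not (c.islower() or c == ".")) for seq in records]
    master_len = len(flattened[0])
    for i, seq in enumerate(flattened):
        if len(seq) != master_len:
            raise ValueError(
                f"record {i} flattens to length {len(seq)}, master length is {master_len}"
            )
    return RawAlignment(flattened)


def encode_msa(
    aln: RawAlignment,
    vocab: ResidueVocabulary = DEFAULT_VOCABULARY,
    depth_cap: int = 1000,
) -> EncodedMSA:
    """Integer-encode the top `depth_cap` sequences, zero-padding the rest.

    The "top" sequences are simply the first in file order (the order the
    alignment software emitted). If fewer than `depth_cap` sequences exist,
    all-zero rows are appended at the bottom.
    """
    if depth_cap < 1:
        raise ValueError("depth_cap must be >= 1")
    n_used = min(aln.n_sequences, depth_cap)
    values = np.zeros((depth_cap, aln.length), dtype=np.int64)
    for row in range(n_used):
        values[row] = vocab.encode(aln.sequences[row])
    return EncodedMSA(values=values, n_sequences=aln.n_sequences)


def _blosum62_scores_against_master(
    rows: list[str], master: str
) -> np.ndarray:
    matrix = substitution_matrices.load("BLOSUM62")
    alphabet = set(matrix.alphabet)

    def lookup(a: str, b: str) -> float:
        a = a if a in alphabet else "X"
        b = b if b in alphabet else "X"
        return float(matrix[a, b])

    scores = np.empty(len(rows))
    for r, seq in enumerate(rows):
        total = 0.0
        for a, b in zip(seq, master):
            if a != GAP and b != GAP:
                total += lookup(a, b)
        scores[r] = total
    return scores


def reorder_sequences(msa, mode: str = "native", seed: int = 0):
    """Reorder non-master rows; the master always stays at row 0.

    Modes: ``native`` (identity), ``blosum62_sort`` (descending sum of
    BLOSUM62 scores against the master over gap-free positions, stable) and
    ``shuffle`` (seeded permutation). Accepts a RawAlignment or EncodedMSA
    and returns the same type.
    """
    if mode not in ("native", "blosum62_sort", "shuffle"):
        raise ValueError(f"unknown reorder mode {mode!r}")
    if mode == "native":
        return msa

    if isinstance(msa, RawAlignment):
        rows = list(msa.sequences[1:])
        master = msa.master
    elif isinstance(msa, EncodedMSA):
        n_real = min(msa.n_sequences, msa.depth)
        vocab = DEFAULT_VOCABULARY
        rows = [vocab.decode(msa.values[r]) for r in range(1, n_real)]
        master = vocab.decode(msa.values[0])
    else:
        raise TypeError("expected RawAlignment or EncodedMSA")

    if mode == "shuffle":
        order = np.random.default_rng(seed).permutation(len(rows))
    else:
        scores = _blosum62_scores_against_master(rows, master)
        order = np.argsort(-scores, kind="stable")

    if isinstance(msa, RawAlignment):
        return RawAlignment([master] + [rows[i] for i in order])
    reordered = msa.values.copy()
    for new_pos, old in enumerate(order, start=1):
        reordered[new_pos] = msa.values[1 + old]
    return EncodedMSA(values=reordered, n_sequences=msa.n_sequences)


def extract_windows(msa: EncodedMSA, width: int = 31) -> list[MSAWindow]:
    """Cut one (Y, width) window per master residue, zero-padded at the ends.

    Window i spans master columns i-width//2 .. i+width//2; columns falling
    outside the sequence are all-zero.
    """
    if width % 2 == 0:
        raise ValueError("window width must be odd")
    half = width // 2
    depth, length = msa.values.shape
    padded = np.zeros((depth, length + 2 * half), dtype=msa.values.dtype)
    padded[:, half : half + length] = msa.values
    return [
        MSAWindow(values=padded[:, i : i + width].copy(), center=i)
        for i in range(length)
    ]
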