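"""Ground-truth labels: secondary structure, solvent accessibility, contacts.

Secondary structure and accessible surface areas come from DSSP output
files (DSSP itself is not run here). The eight DSSP states collapse to the
common three classes; RSA is the DSSP absolute area divided by the
residue's theoretical maximum accessible surface area. Contacts are
residue pairs whose representative atoms (Cβ, Cα for glycine) lie strictly
within 8 Å.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DsspRecord",
    "StructureLabels",
    "ContactMap",
    "THEORETICAL_MAX_ASA",
    "parse_dssp",
    "reduce_ss8_to_ss3",
    "compute_rsa",
    "classify_rsa",
    "contact_map_from_coords",
    "representative_atom_coords",
    "long_range_pairs",
    "labels_from_dssp",
    "write_labels_tsv",
    "write_rr",
    "read_rr",
]

# Theoretical maximum accessible surface areas (Å^2) per residue, used to
# normalize DSSP absolute areas into relative solvent accessibility.
# Supplied as configuration; override by passing your own table.
THEORETICAL_MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

SS8_TO_SS3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "S": "C", "T": "C", "C": "C", " ": "C",
}

RSA4_CLASSES = ("Buried", "PartiallyBuried", "PartiallyAccessible", "Accessible")
RSA2_CLASSES = ("Buried", "Accessible")

CONTACT_CUTOFF = 8.0
LONG_RANGE_MIN_SEPARATION = 24  # "over 23"


@dataclass
class DsspRecord:
    residue: str
    chain: str
    ss8: str
    asa: float
    resnum: str


@dataclass
class StructureLabels:
    """Per-residue labels: SS3 class, RSA fraction, 4-class and 2-class RSA."""

    ss3: np.ndarray
    rsa: np.ndarray
    rsa4: np.ndarray
    rsa2: np.ndarray

    def __post_init__(self):
        n = len(self.ss3)
        if not (len(self.rsa) == len(self.rsa4) == len(self.rsa2) == n):
            raise ValueError("label arrays must share one length")

    @property
    def length(self) -> int:
        return len(self.ss3)


@dataclass
class ContactMap:
    """Symmetric L x L binary map; `mask` flags residues with coordinates.

    The diagonal is 1 (self-distance 0 is below any cutoff) but is never
    used in evaluation.
    """

    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact map must be square")
        if self.mask is None:
            self.mask = np.ones(self.values.shape[0], dtype=bool)

    @property
    def length(self) -> int:
        return self.values.shape[0]


def parse_dssp(path) -> list[DsspRecord]:
    """Parse a DSSP output file into per-residue records, in file order.

    Chain-break rows (``!`` in the amino-acid column) are skipped; a blank
    structure column is reported as coil (C).
    """
    with open(path) as fh:
        lines = fh.readlines()
    start = None
    for i, line in enumerate(lines):
        if line.startswith("  #  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise ValueError("not a DSSP file: data section header missing")
    records: list[DsspRecord] = []
    for line in lines[start:]:
        if len(line.rstrip("\n")) < 38:
            raise ValueError(f"unparseable DSSP row: {line!r}")
        aa = line[13]
        if aa == "!":
            continue
        ss8 = line[16]
        if ss8 == " ":
            ss8 = "C"
        try:
            asa = float(line[34:38])
        except ValueError as exc:
            raise ValueError(f"unparseable ACC field in DSSP row: {line!r}") from exc
        records.append(
            DsspRecord(
                residue=aa,
                chain=line[11],
                ss8=ss8,
                asa=asa,
                resnum=line[5:10].strip(),
            )
        )
    return records


def reduce_ss8_to_ss3(ss8: str) -> str:
    """Collapse the eight DSSP states to {H, E, C}: helices (H, G, I) to H,
    strands and bridges (E, B) to E, everything else to coil."""
    if ss8 not in SS8_TO_SS3:
        raise ValueError(f"unknown DSSP state {ss8!r}")
    return SS8_TO_SS3[ss8]


def compute_rsa(
    asa: float, residue: str, table: dict[str, float] | None = None
) -> float:
    """Relative solvent accessibility = ASA / MaxASA(residue), clipped to 1."""
    table = THEORETICAL_MAX_ASA if table is None else table
    if residue not in table:
        raise KeyError(f"residue {residue!r} absent from MaxASA table")
    if asa < 0:
        raise ValueError("ASA must be non-negative")
    return min(asa / table[residue], 1.0)


def classify_rsa(rsa: float, scheme: str = "four") -> str:
    """Bin an RSA fraction: four classes at (0.04, 0.25, 0.5], two at 0.25.

    Intervals are right-closed: rsa == 0.04 is Buried in the four-class
    scheme, rsa == 0.25 is Buried in the two-class scheme.
    """
    if not 0.0 <= rsa <= 1.0:
        raise ValueError("rsa must be in [0, 1]")
    if scheme == "four":
        if rsa <= 0.04:
            return "Buried"
        if rsa <= 0.25:
            return "PartiallyBuried"
        if rsa <= 0.5:
            return "PartiallyAccessible"
        return "Accessible"
    if scheme == "two":
        return "Buried" if rsa <= 0.25 else "Accessible"
    raise ValueError(f"unknown RSA scheme {scheme!r}")


def labels_from_dssp(
    records: list[DsspRecord], table: dict[str, float] | None = None
) -> StructureLabels:
    """Build the full per-residue label set from parsed DSSP records.

    Lowercase DSSP amino-acid codes (SS-bonded cysteines) count as C.
    """
    ss3, rsa, rsa4, rsa2 = [], [], [], []
    for rec in records:
        aa = "C" if rec.residue.islower() else rec.residue
        ss3.append(reduce_ss8_to_ss3(rec.ss8))
        frac = compute_rsa(rec.asa, aa, table)
        rsa.append(frac)
        rsa4.append(classify_rsa(frac, "four"))
        rsa2.append(classify_rsa(frac, "two"))
    return StructureLabels(
        ss3=np.array(ss3), rsa=np.array(rsa), rsa4=np.array(rsa4), rsa2=np.array(rsa2)
    )


def contact_map_from_coords(
    coords: np.ndarray, cutoff: float = CONTACT_CUTOFF
) -> ContactMap:
    """Binary contact map: 1 iff the representative-atom distance is
    strictly below `cutoff`. Rows with missing (NaN) coordinates are masked
    and excluded from evaluation downstream."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (L, 3)")
    mask = ~np.isnan(coords).any(axis=1)
    if not mask.any():
        raise ValueError("no coordinates present")
    safe = np.where(mask[:, None], coords, 0.0)
    diff = safe[:, None, :] - safe[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    values = (dist < cutoff).astype(np.int8)
    values[~mask, :] = 0
    values[:, ~mask] = 0
    return ContactMap(values=values, mask=mask)


def representative_atom_coords(pdb_path, chain_id: str | None = None):
    """Per-residue Cβ coordinates (Cα for glycine) from a PDB file.

    Residues missing the representative atom get NaN coordinates and are
    masked in the resulting contact map. AltLoc disambiguation (highest
    occupancy, first on tie) follows the Biopython parser default.
    Returns (coords (L,3), one-letter residue codes).
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import protein_letters_3to1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("x", str(pdb_path))
    model = next(structure.get_models())
    chains = list(model.get_chains())
    if chain_id is not None:
        chains = [c for c in chains if c.id == chain_id]
        if not chains:
            raise ValueError(f"chain {chain_id!r} not found")
    coords, codes = [], []
    for chain in chains:
        for res in chain.get_residues():
            if res.id[0] != " ":  # skip HETATM / waters
                continue
            code = protein_letters_3to1.get(res.get_resname(), "X")
            atom_name = "CA" if res.get_resname() == "GLY" else "CB"
            if atom_name in res:
                coords.append(res[atom_name].get_coord())
            elif "CA" in res:  # e.g. Cβ missing from the model
                coords.append(res["CA"].get_coord())
            else:
                coords.append(np.array([np.nan] * 3))
            codes.append(code)
    return np.asarray(coords, dtype=float), codes


def long_range_pairs(length: int) -> set[tuple[int, int]]:
    """All unordered 1-based pairs with sequence separation over 23."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return {
        (i, j)
        for i in range(1, length + 1)
        for j in range(i + LONG_RANGE_MIN_SEPARATION, length + 1)
    }


def write_labels_tsv(labels: StructureLabels, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tss3\trsa\trsa4\trsa2\n")
        for i in range(labels.length):
            fh.write(
                f"{i + 1}\t{labels.ss3[i]}\t{labels.rsa[i]:.4f}"
                f"\t{labels.rsa4[i]}\t{labels.rsa2[i]}\n"
            )


def write_rr(probabilities: np.ndarray, path, min_separation: int = 1) -> None:
    """Write a CASP-RR-style contact file: ``i j 0 8 prob`` (1-based, i<j),
    sorted by probability descending."""
    probabilities = np.asarray(probabilities)
    length = probabilities.shape[0]
    rows = [
        (i + 1, j + 1, probabilities[i, j])
        for i in range(length)
        for j in range(i + min_separation, length)
    ]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w") as fh:
        for i, j, p in rows:
            fh.write(f"{i} {j} 0 8 {p:.6f}\n")


def read_rr(path, length: int) -> np.ndarray:
    """Read a CASP-RR-style file into a symmetric (L, L) probability map."""
    values = np.zeros((length, length))
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 5:
                continue
            i, j, p = int(parts[0]) - 1, int(parts[1]) - 1, float(parts[4])
            values[i, j] = values[j, i] = p
    return values
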