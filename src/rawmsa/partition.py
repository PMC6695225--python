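"""Homolog-safe dataset partitioning via structural superfamilies.

Sequence-identity thresholds leak homologous information between training
and test sets; instead, chains are assigned to cross-validation folds so
that no structural superfamily (ECOD/SCOPe-style) ever spans two folds.
Chains mapping to more than one superfamily (or to none) are removed.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "filter_single_superfamily",
    "split_by_superfamily",
    "read_superfamily_table",
    "write_fold_lists",
]


def filter_single_superfamily(assignments: dict[str, set[str]]) -> list[str]:
    """Keep exactly the chains assigned to a single superfamily."""
    return [chain for chain, sfs in assignments.items() if len(sfs) == 1]


def split_by_superfamily(
    chains: dict[str, str], k: int = 5, seed: int = 0
) -> dict[str, int]:
    """Assign whole superfamilies to folds 1..k by greedy size balancing.

    Superfamilies are placed largest-first into the currently smallest fold;
    the seed shuffles the order among equal-sized superfamilies (and the
    fold scan order is fixed, so ties in fold size go to the lowest index).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    by_sf: dict[str, list[str]] = {}
    for chain, sf in chains.items():
        by_sf.setdefault(sf, []).append(chain)
    if len(by_sf) < k:
        warnings.warn(
            f"only {len(by_sf)} superfamilies for {k} folds; some folds will be empty",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    sfs = list(by_sf)
    rng.shuffle(sfs)
    sfs.sort(key=lambda s: -len(by_sf[s]))  # stable: shuffled order breaks ties
    fold_sizes = [0] * k
    split: dict[str, int] = {}
    for sf in sfs:
        fold = int(np.argmin(fold_sizes))
        for chain in by_sf[sf]:
            split[chain] = fold + 1
        fold_sizes[fold] += len(by_sf[sf])
    return split


def read_superfamily_table(path) -> dict[str, set[str]]:
    """Read a tab-separated chain-id / superfamily-id table (one pair per
    line; repeated chain ids accumulate)."""
    assignments: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed superfamily row: {line!r}")
            assignments.setdefault(parts[0], set()).add(parts[1])
    return assignments


def write_fold_lists(split: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tfold\n")
        for chain in sorted(split):
            fh.write(f"{chain}\t{split[chain]}\n")
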