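"""Desk-scale learnability experiments on the synthetic generators.

These run the full pipeline — generate alignments with planted signal,
encode, train a small network, evaluate on held-out proteins — at sizes a
single CPU handles in a few minutes. They are the package's self-contained
evidence that the architectures extract the intended signal from raw
alignments; see docs/methods.md for what they do and do not show about
real proteins.
"""

from __future__ import annotations

import numpy as np

from .ensembling import symmetrize
from .estimators import ContactMapNet, SecondaryStructureNet
from .evaluation import random_long_range_baseline, top_l5_long_range_precision
from .msa import encode_msa
from .synthetic import SyntheticConfig, generate_contact_msa, generate_ss_msa

__all__ = ["ss_learnability_experiment", "contact_learnability_experiment"]


def _sub_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _ss_dataset(seeds, L: int, N: int, depth_cap: int):
    X, y = [], []
    for s in seeds:
        aln, labels = generate_ss_msa(SyntheticConfig(L=L, N=N, seed=int(s)))
        X.append(encode_msa(aln, depth_cap=depth_cap))
        y.append(labels.ss3)
    return X, y


def ss_learnability_experiment(
    seed: int = 0,
    n_train: int = 160,
    n_test: int = 20,
    L: int = 60,
    N: int = 30,
    depth_cap: int = 20,
    epochs: int = 5,
) -> dict:
    """Train a small window classifier on planted-composition alignments.

    Returns held-out Q3, the majority-class baseline on the same held-out
    residues, and the training-set size in residues.
    """
    seeds = _sub_seeds(seed, n_train + n_test)
    Xtr, ytr = _ss_dataset(seeds[:n_train], L, N, depth_cap)
    Xte, yte = _ss_dataset(seeds[n_train:], L, N, depth_cap)
    est = SecondaryStructureNet(
        embedding_dim=8,
        depth_cap=depth_cap,
        lstm_units=16,
        pool_window=4,
        filters=16,
        dense_units=(64,),
        dropout=0.0,
        epochs=epochs,
        learning_rate=3e-3,
        random_state=seed,
    )
    est.fit(Xtr, ytr)
    q3 = est.score(Xte, yte)
    all_test = np.concatenate(yte)
    majority = max(float(np.mean(all_test == c)) for c in np.unique(all_test))
    return {
        "q3": q3,
        "majority_baseline": majority,
        "n_train_residues": sum(len(t) for t in ytr),
        "n_test_proteins": n_test,
        "history": est.history_.epochs,
    }


def contact_learnability_experiment(
    seed: int = 0,
    n_train: int = 40,
    n_test: int = 6,
    L: int = 60,
    N: int = 24,
    epochs: int = 25,
) -> dict:
    """Train a small pair network on planted-covariation alignments.

    Returns the mean held-out top-L/5 long-range precision, the expected
    precision of a random ranking (the long-range contact density), and
    their ratio.
    """
    seeds = _sub_seeds(seed + 1, n_train + n_test)

    def dataset(ss):
        X, y = [], []
        for s in ss:
            aln, cmap = generate_contact_msa(SyntheticConfig(L=L, N=N, seed=int(s)))
            X.append(encode_msa(aln, depth_cap=N))
            y.append(cmap)
        return X, y

    Xtr, ytr = dataset(seeds[:n_train])
    Xte, yte = dataset(seeds[n_train:])
    est = ContactMapNet(
        embedding_dim=4,
        depth_cap=N,
        pool_window=2,
        filters=8,
        n_column_stages=1,
        trunk_depth=3,
        trunk_filters=8,
        epochs=epochs,
        patience=None,
        learning_rate=1e-3,
        random_state=seed,
    )
    est.fit(Xtr, ytr)
    probs = est.predict_proba(Xte)
    precisions = [
        top_l5_long_range_precision(symmetrize(p), t) for p, t in zip(probs, yte)
    ]
    baselines = [random_long_range_baseline(t) for t in yte]
    precision = float(np.mean(precisions))
    baseline = float(np.mean(baselines))
    return {
        "top_l5_precision": precision,
        "random_baseline": baseline,
        "ratio": precision / baseline if baseline > 0 else float("inf"),
        "n_test_proteins": n_test,
        "history": est.history_.epochs,
    }
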