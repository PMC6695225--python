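"""Softmax-averaging ensembles.

Class predictions from several trained models (and, for contacts, from
several alignment sources per target) are combined by arithmetic mean of
the softmax outputs; the winning class is the one with the highest average
probability. Contact maps are additionally symmetrized by pair averaging,
(P[i,j] + P[j,i]) / 2, before any ranking.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ensemble_average", "symmetrize", "predict_contacts_ensemble"]

_SIMPLEX_TOL = 1e-4


def ensemble_average(distributions: list[np.ndarray]) -> tuple[np.ndarray, int]:
    """Mean of class-probability vectors and the argmax class (lowest index
    wins ties). Inputs must be simplex vectors of one shared length."""
    if not distributions:
        raise ValueError("no distributions to ensemble")
    arrays = [np.asarray(d, dtype=float) for d in distributions]
    n = arrays[0].shape[-1]
    for a in arrays:
        if a.shape != arrays[0].shape:
            raise ValueError("distributions have mismatched lengths")
        if (a < -_SIMPLEX_TOL).any() or abs(float(a.sum()) - 1.0) > _SIMPLEX_TOL * n:
            raise ValueError("input is not a probability distribution")
    mean = np.mean(arrays, axis=0)
    return mean, int(np.argmax(mean))


def symmetrize(pair_map: np.ndarray) -> np.ndarray:
    pair_map = np.asarray(pair_map)
    return (pair_map + pair_map.T) / 2.0


def predict_contacts_ensemble(models: list, alignments: list) -> np.ndarray:
    """Ensemble contact probabilities over models x alignment sources.

    `alignments` holds one encoded alignment per source (e.g. from two
    different aligners) for the *same* target; their master rows must agree
    exactly, otherwise the prediction fails loudly. The returned L x L map
    is the mean contact-class probability, symmetrized by pair averaging.
    """
    if not models:
        raise ValueError("no models in ensemble")
    if not alignments:
        raise ValueError("no alignments provided")
    values = [np.asarray(getattr(a, "values", a)) for a in alignments]
    master = values[0][0]
    for v in values[1:]:
        if v.shape[1] != values[0].shape[1] or not np.array_equal(v[0], master):
            raise ValueError(
                "alignment sources disagree on the master sequence; refusing to ensemble"
            )
    maps = []
    for model in models:
        predictor = getattr(model, "model_", model)  # estimator or bare network
        for v in values:
            maps.append(predictor.predict_proba(v))
    return symmetrize(np.mean(maps, axis=0))
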