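"""SVM-guided synthetic minority oversampling (SVM-SMOTE).

Balances error vs correct classes by synthesizing minority samples near the
decision boundary of an SVM fitted to the training data: minority support
vectors in the "danger zone" (a majority-dominated m-neighborhood) spawn
SMOTE interpolations toward nearby minority samples, while safe support
vectors spawn bounded extrapolations away from them, pushing the synthetic
cloud toward the boundary.  Original rows are always preserved verbatim and
first; the majority class is untouched.

The training module applies this per cross-validation iteration — never to
a full dataset — so validation folds stay disjoint from anything the
oversampler saw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .io_store import EpochSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OversampleConfig:
    """SVM-SMOTE knobs (defaults follow the technique's common usage)."""

    k_neighbors: int = 5
    m_neighbors: int = 10
    svm_regularization: float = 1.0
    extrapolation_step: float = 0.5
    enabled: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.k_neighbors < 1 or self.m_neighbors < 1:
            raise ValueError("neighbor counts must be positive")
        if self.svm_regularization <= 0:
            raise ValueError("svm_regularization must be positive")
        if not 0.0 <= self.extrapolation_step <= 1.0:
            raise ValueError("extrapolation_step must be in [0, 1]")


def flatten_for_oversampling(epochset: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Flatten canonical (2, 64) epochs row-major to (n, 128) features.

    Element (c, t) of epoch i lands in column ``c * 64 + t`` of row i.
    """
    epochset.validate_canonical()
    n = len(epochset)
    return (epochset.data.reshape(n, 128).astype(np.float64),
            epochset.labels.astype(np.int64).copy())


def reshape_from_oversampling(features: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten_for_oversampling`: (n, 128) -> (n, 2, 64)."""
    features = np.asarray(features)
    if features.ndim != 2 or features.shape[1] != 128:
        raise ValueError(f"expected (n, 128) features, got {features.shape}")
    return features.reshape(-1, 2, 64)


def svm_smote(
    features: np.ndarray,
    labels: np.ndarray,
    config: OversampleConfig = OversampleConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a binary problem by SVM-guided SMOTE.

    Returns ``(features_out, labels_out)`` where the minority count equals
    the majority count, the original rows appear first and unmodified, and
    every synthetic row is an affine combination ``x_i + lam * (x_j - x_i)``
    of two original minority rows with ``lam`` in
    ``[-extrapolation_step, 1]``.  Deterministic given ``config.seed``.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels).astype(np.int64).reshape(-1)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return features.copy(), labels.copy()
    if n_min <= config.k_neighbors:
        raise ValueError(
            f"minority count {n_min} must exceed k_neighbors={config.k_neighbors}")

    rng = np.random.default_rng(config.seed)
    min_x = features[labels == minority]

    svm = SVC(kernel="rbf", C=config.svm_regularization, gamma="scale",
              random_state=config.seed)
    svm.fit(features, labels)
    sv_mask = labels[svm.support_] == minority
    seeds = features[svm.support_[sv_mask]]
    if seeds.shape[0] == 0:
        # no minority support vectors (degenerate geometry): fall back to
        # plain SMOTE over all minority rows
        seeds = min_x
        danger = np.ones(len(seeds), dtype=bool)
        logger.warning("no minority support vectors; falling back to plain SMOTE")
    else:
        m = min(config.m_neighbors, len(features) - 1)
        nn_all = NearestNeighbors(n_neighbors=m + 1).fit(features)
        _, idx = nn_all.kneighbors(seeds)
        # drop the self column when the seed is among its own neighbors
        neigh_labels = labels[idx[:, 1:]]
        maj_frac = (neigh_labels != minority).mean(axis=1)
        noise = maj_frac == 1.0  # isolated in majority territory: skip
        danger = (maj_frac >= 0.5) & ~noise
        if noise.any():
            seeds, danger = seeds[~noise], danger[~noise]
        if seeds.shape[0] == 0:
            seeds = min_x
            danger = np.ones(len(seeds), dtype=bool)

    k = min(config.k_neighbors, n_min - 1)
    nn_min = NearestNeighbors(n_neighbors=k + 1).fit(min_x)
    _, min_idx = nn_min.kneighbors(seeds)

    synth = np.empty((n_new, features.shape[1]))
    seed_choice = rng.integers(0, len(seeds), size=n_new)
    neigh_choice = rng.integers(1, k + 1, size=n_new)  # skip the self column
    u = rng.random(n_new)
    for row, (s_i, n_i) in enumerate(zip(seed_choice, neigh_choice)):
        x = seeds[s_i]
        neighbor = min_x[min_idx[s_i, n_i]]
        if danger[s_i]:
            lam = u[row]  # interpolate toward the minority neighbor
        else:
            lam = -config.extrapolation_step * u[row]  # extrapolate away
        synth[row] = x + lam * (neighbor - x)

    features_out = np.vstack([features, synth])
    labels_out = np.concatenate([labels, np.full(n_new, minority, dtype=np.int64)])
    return features_out, labels_out


def oversample_epochs(
    data: np.ndarray, labels: np.ndarray, config: OversampleConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience wrapper: (n, 2, 64) epochs in, balanced epochs out."""
    n = data.shape[0]
    feats, labs = svm_smote(data.reshape(n, -1).astype(np.float64), labels, config)
    return feats.reshape(-1, *data.shape[1:]), labs
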