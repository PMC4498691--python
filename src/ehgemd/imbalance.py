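"""SMOTE oversampling of the minority (preterm) class.

The TPEHG cohort is 262 term vs 38 preterm records; classifiers trained on
it directly favour the majority class.  SMOTE balances the classes by
synthesizing minority points: take a minority row x, pick one of its k
nearest minority neighbours nn, and emit x + u (nn - x) with u uniform in
[0, 1].  Every synthetic row is therefore an exact convex combination of two
original minority rows, which keeps synthetic feature values inside the
minority class's per-feature range.

Canonical SMOTE defines only integer oversampling rates; 38 -> 262 is a
factor of ~6.9, so the synthetic counts are spread as evenly as possible
across the minority rows (each seed row used floor or ceil of the mean
count), hitting the target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .entropy_features import FeatureMatrix

__all__ = ["SmoteConfig", "smote_synthesize", "balance_dataset"]


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    target_count: Union[int, str] = "match-majority"
    seed: int = 0
    standardize: bool = False  # z-score features before the neighbour search

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def smote_synthesize(minority: np.ndarray, config: SmoteConfig) -> np.ndarray:
    """Synthesize ``target_count - n_minority`` rows by neighbour interpolation.

    ``config.target_count`` must be an integer here (``balance_dataset``
    resolves "match-majority").  Fully reproducible from ``config.seed``.
    """
    X = np.atleast_2d(np.asarray(minority, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("SMOTE needs at least 2 minority rows (no neighbour exists)")
    if not isinstance(config.target_count, (int, np.integer)):
        raise ValueError("target_count must be resolved to an integer")
    n_new = int(config.target_count) - n
    if n_new < 0:
        raise ValueError(
            f"target_count {config.target_count} below current minority count {n}"
        )
    if n_new == 0:
        return np.empty((0, X.shape[1]))

    k = min(config.k_neighbors, n - 1)
    Xq = X
    if config.standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xq = (X - X.mean(axis=0)) / sd
    # k+1 because each point is its own nearest neighbour
    nn_idx = (
        NearestNeighbors(n_neighbors=k + 1).fit(Xq).kneighbors(Xq, return_distance=False)[:, 1:]
    )

    rng = np.random.default_rng(config.seed)
    # spread counts evenly: each seed row used floor(n_new/n) or one more
    counts = np.full(n, n_new // n)
    extra = rng.permutation(n)[: n_new % n]
    counts[extra] += 1

    rows = []
    for i in range(n):
        for _ in range(counts[i]):
            j = nn_idx[i, rng.integers(k)]
            u = rng.random()
            rows.append(X[i] + u * (X[j] - X[i]))
    return np.vstack(rows) if rows else np.empty((0, X.shape[1]))


def balance_dataset(matrix: FeatureMatrix, config: SmoteConfig) -> FeatureMatrix:
    """Augment the minority class of ``matrix`` to the target count.

    Majority rows are untouched; synthetic rows carry the minority label and
    ``origin == "synthetic"``.  An already balanced matrix is returned as-is.
    """
    counts = matrix.class_counts()
    if len(counts) != 2:
        raise ValueError(f"need exactly 2 classes, got {sorted(counts)}")
    (lab_a, n_a), (lab_b, n_b) = sorted(counts.items(), key=lambda kv: kv[1])
    minority_label, majority_count = lab_a, n_b
    target = (
        majority_count if config.target_count == "match-majority"
        else int(config.target_count)
    )
    if target < n_a:
        raise ValueError(f"target_count {target} below minority count {n_a}")
    if target == n_a:
        return matrix

    mask = np.array([lab == minority_label for lab in matrix.labels])
    synth = smote_synthesize(matrix.data[mask], replace(config, target_count=target))
    n_new = synth.shape[0]
    return FeatureMatrix(
        data=np.vstack([matrix.data, synth]),
        labels=matrix.labels + [minority_label] * n_new,
        feature_names=matrix.feature_names,
        record_ids=matrix.record_ids
        + [f"smote_{minority_label}_{i}" for i in range(n_new)],
        origin=matrix.origin + ["synthetic"] * n_new,
        skipped=matrix.skipped,
    )
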