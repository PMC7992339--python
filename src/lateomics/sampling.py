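"""SMOTE oversampling to balance binary classes before training.

Synthetic minority samples are drawn on the segment between a minority
sample and one of its k nearest minority neighbours:

    x_new = x_i + u * (x_nn - x_i),   u ~ Uniform(0, 1)

Original samples are preserved verbatim and come first in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass
class SmoteParams:
    k_neighbors: int = 5
    target_ratio: float = 1.0  # minority/majority ratio after balancing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0 < self.target_ratio <= 1:
            raise ValueError("target_ratio must lie in (0, 1]")


def smote(X, y, params: SmoteParams | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class of a binary problem.

    Returns (X', y') with the original rows first, followed by synthetic
    minority rows until minority count = round(target_ratio * majority
    count).  With target_ratio=1 the output has exactly 2 * majority_count
    rows (e.g. a 266/48 split balances 314 samples up to 532).
    """
    params = params or SmoteParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"smote requires exactly two classes, got {len(classes)}")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    target = int(round(params.target_ratio * n_maj))
    n_new = target - n_min
    if n_new <= 0:
        return X.copy(), y.copy()
    if n_min <= params.k_neighbors:
        raise ValueError(
            f"minority count {n_min} must exceed k_neighbors={params.k_neighbors}"
        )
    rng = np.random.default_rng(params.seed)
    X_min = X[y == minority]
    nn = NearestNeighbors(n_neighbors=params.k_neighbors + 1).fit(X_min)
    # first neighbour is the point itself; keep the k true neighbours
    neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    parents = rng.integers(0, n_min, size=n_new)
    picks = rng.integers(0, params.k_neighbors, size=n_new)
    u = rng.random(n_new)
    anchors = X_min[parents]
    partners = X_min[neigh[parents, picks]]
    synthetic = anchors + u[:, None] * (partners - anchors)
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out
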