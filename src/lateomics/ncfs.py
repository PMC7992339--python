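"""Neighborhood component analysis feature selection (NCFS).

Learns a nonnegative per-feature weight vector ``w`` — the diagonal
specialization of the quadratic (Mahalanobis-type) metric

    d_w(x_i, x_j) = sum_l w_l^2 (x_il - x_jl)^2

by maximizing a softmax-weighted leave-one-out neighbour agreement.  With
the kernel kappa(z) = exp(-z / sigma), reference-point probabilities are

    p_ij = kappa(d_w(x_i, x_j)) / sum_{k != i} kappa(d_w(x_i, x_k)),  p_ii = 0

and the regularized objective is

    classification:  f(w) = sum_i sum_{j : y_j = y_i} p_ij  -  lambda * sum_l w_l^2
    regression:      f(w) = -sum_i sum_j p_ij |y_i - y_j|   -  lambda * sum_l w_l^2

maximized by gradient ascent with adaptive step halving from w = 1.
Irrelevant features are driven towards zero weight by the L2 penalty;
informative features retain large weights and are selected by rank or by a
threshold relative to the maximum weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_MAX_EXPONENT = 700.0  # reference scale for kernel exponents (stability shift applied per row)


@dataclass
class NCFSParams:
    """Hyperparameters of the NCFS fit.

    sigma is the kernel width; None (default) auto-scales it at fit time to
    the mean off-diagonal pairwise distance at the initial weights, which
    keeps the softmax informative for any feature count.  lam is the L2
    weight penalty, defaulting to 1/n_samples when None at fit time.
    """

    sigma: float | None = None
    lam: float | None = None
    learning_rate: float = 1.0
    max_iter: int = 100
    tol: float = 1e-6
    task: str = "classification"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.task not in ("classification", "regression"):
            raise ValueError("task must be 'classification' or 'regression'")


@dataclass
class FeatureWeights:
    """Fitted NCFS results: weights, objective trace and the parameters used."""

    w: np.ndarray
    objective_trace: list[float]
    params: NCFSParams
    feature_ids: list | None = None

    def __post_init__(self) -> None:
        if (self.w < 0).any():
            raise ValueError("weights must be nonnegative")

    def select(self, rule: str = "weight_above", k: int | None = None, tau: float = 0.1) -> list[int]:
        return select_features(self, rule=rule, k=k, tau=tau)

    def summary(self) -> pd.DataFrame:
        ids = self.feature_ids if self.feature_ids is not None else list(range(len(self.w)))
        df = pd.DataFrame({"feature_id": ids, "weight": self.w})
        return df.sort_values("weight", ascending=False, kind="stable").reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)


def ncfs_distance(xi: np.ndarray, xj: np.ndarray, w: np.ndarray) -> float:
    """Weighted squared distance sum_l w_l^2 (x_il - x_jl)^2."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    w = np.asarray(w, dtype=float)
    if xi.shape != xj.shape or xi.shape != w.shape:
        raise ValueError(
            f"length mismatch: xi {xi.shape}, xj {xj.shape}, w {w.shape}"
        )
    return float(np.sum(w**2 * (xi - xj) ** 2))


def _pairwise_weighted_sq(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """All-pairs d_w as an n x n matrix, via the scaled-coordinates trick."""
    Xw = X * w  # scaling coordinates by w makes d_w the plain squared distance
    sq = np.sum(Xw**2, axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * (Xw @ Xw.T)
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def _reference_probs(d: np.ndarray, sigma: float) -> np.ndarray:
    """Row-stochastic p_ij from pairwise distances; p_ii = 0.

    Each row is shifted by its minimum off-diagonal distance before
    exponentiation — exact by kernel-ratio invariance — so p_ij stays finite
    for widely spread data.
    """
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not np.isfinite(d).all():
        raise ValueError(
            "pairwise distances overflow the kernel; increase sigma or rescale features"
        )
    off = d + np.diag(np.full(n, np.inf))
    row_min = off.min(axis=1)
    shifted = (d - row_min[:, None]) / sigma
    np.fill_diagonal(shifted, np.inf)  # excludes p_ii and avoids exp overflow
    k = np.exp(-shifted)
    return k / k.sum(axis=1, keepdims=True)


def _affinity(y: np.ndarray, task: str) -> np.ndarray:
    """a_ij: 1 for same-class pairs (classification), -|y_i - y_j| (regression)."""
    y = np.asarray(y)
    if task == "classification":
        return (y[:, None] == y[None, :]).astype(float)
    y = y.astype(float)
    return -np.abs(y[:, None] - y[None, :])


def _resolve_sigma(params: NCFSParams, d: np.ndarray) -> float:
    if params.sigma is not None:
        return params.sigma
    n = d.shape[0]
    off = d[~np.eye(n, dtype=bool)]
    m = float(off.mean())
    return m if m > 0 else 1.0


def ncfs_objective(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, params: NCFSParams
) -> tuple[float, np.ndarray]:
    """Regularized LOO objective and the p_ij grid at weight vector w."""
    X = np.asarray(X, dtype=float)
    lam = 1.0 / X.shape[0] if params.lam is None else params.lam
    d = _pairwise_weighted_sq(X, np.asarray(w, dtype=float))
    p = _reference_probs(d, _resolve_sigma(params, d))
    a = _affinity(y, params.task)
    f = float(np.sum(p * a) - lam * np.sum(np.asarray(w) ** 2))
    return f, p


def ncfs_gradient(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, params: NCFSParams
) -> np.ndarray:
    """Analytic gradient of :func:`ncfs_objective` with respect to w.

    With A = a * p and r_i = sum_j A_ij,

        df/dw_l = (2 w_l / sigma) * [ sum_i r_i <p_i, D_l> - sum_ij A_ij D_ij,l ]
                  - 2 lambda w_l,   D_ij,l = (x_il - x_jl)^2

    computed in O(n^2 p) through matrix products, never forming the
    n x n x p difference tensor.
    """
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float)
    lam = 1.0 / X.shape[0] if params.lam is None else params.lam
    d = _pairwise_weighted_sq(X, w)
    sigma = _resolve_sigma(params, d)
    p = _reference_probs(d, sigma)
    a = _affinity(y, params.task)
    A = a * p
    r = A.sum(axis=1)
    M = r[:, None] * p - A  # sum_ij M_ij D_ij,l is the bracketed term
    X2 = X**2
    u = M.sum(axis=1)
    v = M.sum(axis=0)
    s = u @ X2 + v @ X2 - 2.0 * np.sum(X * (M @ X), axis=0)
    return (2.0 * w / sigma) * s - 2.0 * lam * w


def ncfs_fit(X, y, params: NCFSParams | None = None, feature_ids=None) -> FeatureWeights:
    """Fit NCFS by gradient ascent with step halving from w = 1.

    Steps that do not improve the objective halve the learning rate and are
    retried; accepted-step objective values are therefore non-decreasing.
    Stops at ``max_iter`` or when the relative objective change falls below
    ``tol``.  Weights are clipped at zero after every step.
    """
    params = params or NCFSParams()
    if isinstance(X, pd.DataFrame):
        feature_ids = feature_ids if feature_ids is not None else list(X.columns)
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    w = np.ones(p)
    if params.sigma is None:
        # freeze the auto kernel width at the initial weights for the whole fit
        from dataclasses import replace as _dc_replace

        d0 = _pairwise_weighted_sq(X, w)
        params = _dc_replace(params, sigma=_resolve_sigma(params, d0))
    step = params.learning_rate
    f, _ = ncfs_objective(X, y, w, params)
    if not np.isfinite(f):
        raise FloatingPointError("objective non-finite at initialization")
    trace = [f]
    for it in range(params.max_iter):
        g = ncfs_gradient(X, y, w, params)
        accepted = False
        while step > 1e-12:
            w_new = np.maximum(w + step * g, 0.0)
            f_new, _ = ncfs_objective(X, y, w_new, params)
            if not np.isfinite(f_new):
                raise FloatingPointError(f"objective non-finite at iteration {it}")
            if f_new >= f:
                accepted = True
                break
            step /= 2.0
        if not accepted:
            break
        rel = abs(f_new - f) / max(abs(f), 1e-12)
        w, f = w_new, f_new
        trace.append(f)
        step *= 1.1  # mild re-expansion after a success
        if rel < params.tol:
            break
    return FeatureWeights(w=w, objective_trace=trace, params=params, feature_ids=feature_ids)


def select_features(
    weights: FeatureWeights, rule: str = "weight_above", k: int | None = None, tau: float = 0.1
) -> list[int]:
    """Pick feature indices by ``top_k`` or ``weight_above`` (tau * max weight).

    Indices come back sorted by descending weight; ties break by ascending
    feature index, so selection is deterministic.
    """
    w = weights.w
    order = np.lexsort((np.arange(len(w)), -w))  # descending weight, then index
    if rule == "top_k":
        if k is None:
            raise ValueError("top_k rule requires k")
        if k > len(w):
            raise ValueError(f"k={k} exceeds the number of features ({len(w)})")
        return [int(i) for i in order[:k]]
    if rule == "weight_above":
        cut = tau * w.max()
        return [int(i) for i in order if w[i] > cut]
    raise ValueError(f"unknown selection rule {rule!r}")
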