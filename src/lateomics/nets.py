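"""Late integration and feed-forward network training.

Selected features from each omics layer are concatenated column-wise (late
integration: three m x n blocks give one m x 3n matrix), optionally followed
by encoded clinical covariates.  On the integrated matrix, small fully
connected networks with tanh hidden layers are trained full-batch:

* survival classifier — two output neurons with a softmax pair, binary
  cross-entropy loss, conjugate-gradient weight updates;
* drug-response regressor — one linear output per drug, mean-squared-error
  loss over observed targets, Levenberg–Marquardt updates (conjugate
  gradient above a parameter-count threshold).

Both minimize the penalized objective

    L = (1 - gamma) * data_term + gamma * mean(theta^2)

where gamma in [0, 1] is the regularization ratio.  k-fold cross-validation
and Gaussian-process Bayesian hyperparameter search (expected improvement)
are layered on top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.stats import norm, pearsonr
from scipy.stats.qmc import LatinHypercube
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel
from sklearn.model_selection import KFold, StratifiedKFold

from .omics_io import MultiOmicsDataset

_PROB_FLOOR = 1e-12  # clamp for log terms in the cross-entropy
_LM_MAX_PARAMS = 250  # beyond this, LM's per-iteration least-squares cost dominates; fall back to CG


# ---------------------------------------------------------------------------
# late integration
# ---------------------------------------------------------------------------

def late_integrate(
    dataset: MultiOmicsDataset,
    selections: Mapping[str, Sequence[int]],
    clinical_spec: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Concatenate selected per-layer columns, then encoded clinical covariates.

    ``selections`` maps layer name -> column indices (declared order is the
    concatenation order).  ``clinical_spec`` may declare ``numeric`` columns
    (passed through) and ``categorical`` columns (one-hot encoded).  Output
    columns are prefixed by their source (``layer:feature``).
    """
    dataset.check_aligned()
    blocks: list[pd.DataFrame] = []
    for layer_name, idx in selections.items():
        layer = dataset.layers[layer_name]
        block = layer.values.iloc[:, list(idx)].copy()
        block.columns = [f"{layer_name}:{c}" for c in block.columns]
        blocks.append(block)
    if clinical_spec:
        clin = dataset.clinical
        for col in list(clinical_spec.get("numeric", [])) + list(clinical_spec.get("categorical", [])):
            if clin is None or col not in clin.columns:
                raise ValueError(f"unknown clinical column {col!r}")
        num = list(clinical_spec.get("numeric", []))
        if num:
            block = clin[num].astype(float).copy()
            block.columns = [f"clinical:{c}" for c in num]
            blocks.append(block)
        for col in clinical_spec.get("categorical", []):
            onehot = pd.get_dummies(clin[col], prefix=f"clinical:{col}").astype(float)
            blocks.append(onehot)
    if not blocks:
        raise ValueError("nothing to integrate: empty selections and no clinical spec")
    return pd.concat(blocks, axis=1)


# ---------------------------------------------------------------------------
# architecture and parameter vector
# ---------------------------------------------------------------------------

@dataclass
class NetArchitecture:
    """Feed-forward layout: tanh hidden layers and a task-specific output.

    ``output`` is ``"classifier"`` (two softmax neurons) or ``"regressor"``
    (``n_outputs`` linear neurons); ``gamma`` is the regularization ratio.
    """

    n_inputs: int
    hidden_layers: Sequence[int] = (7, 7)
    output: str = "classifier"
    n_outputs: int = 2
    gamma: float = 0.1

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_layers):
            raise ValueError("hidden layer sizes must be >= 1")
        if not 0 <= self.gamma <= 1:
            raise ValueError("gamma must lie in [0, 1]")
        if self.output not in ("classifier", "regressor"):
            raise ValueError("output must be 'classifier' or 'regressor'")
        if self.output == "classifier":
            self.n_outputs = 2

    def layer_dims(self) -> list[tuple[int, int]]:
        sizes = [self.n_inputs, *self.hidden_layers, self.n_outputs]
        return list(zip(sizes[:-1], sizes[1:]))

    @property
    def n_params(self) -> int:
        return sum(din * dout + dout for din, dout in self.layer_dims())


def init_params(arch: NetArchitecture, rng: np.random.Generator) -> np.ndarray:
    """Mean-zero symmetric uniform init, scaled by 1/sqrt(fan_in) per layer."""
    chunks = []
    for din, dout in arch.layer_dims():
        s = 1.0 / np.sqrt(din)
        chunks.append(rng.uniform(-s, s, size=din * dout))
        chunks.append(np.zeros(dout))
    return np.concatenate(chunks)


def _unflatten(theta: np.ndarray, arch: NetArchitecture) -> list[tuple[np.ndarray, np.ndarray]]:
    layers = []
    pos = 0
    for din, dout in arch.layer_dims():
        W = theta[pos : pos + din * dout].reshape(din, dout)
        pos += din * dout
        b = theta[pos : pos + dout]
        pos += dout
        layers.append((W, b))
    return layers


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_full(theta: np.ndarray, X: np.ndarray, arch: NetArchitecture):
    """Forward pass keeping hidden activations for backprop."""
    layers = _unflatten(theta, arch)
    activations = [X]
    a = X
    for W, b in layers[:-1]:
        a = np.tanh(a @ W + b)
        activations.append(a)
    W, b = layers[-1]
    z_out = a @ W + b
    out = _softmax(z_out) if arch.output == "classifier" else z_out
    return out, activations, layers


def forward(net: "TrainedNet", X) -> np.ndarray:
    """Evaluate a trained network.

    Classifier: per-sample (p_low, p_high) probabilities summing to 1.
    Regressor: one linear output per target.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != net.architecture.n_inputs:
        raise ValueError(
            f"input has {X.shape[1]} columns; network expects {net.architecture.n_inputs}"
        )
    if net.input_mean is not None:
        X = (X - net.input_mean) / net.input_scale
    out, _, _ = _forward_full(net.params, X, net.architecture)
    return out


# ---------------------------------------------------------------------------
# loss and gradients
# ---------------------------------------------------------------------------

def _data_term_and_delta(out: np.ndarray, targets: np.ndarray, arch: NetArchitecture):
    """Mean data loss and d(loss)/d(output pre-activation)."""
    if arch.output == "classifier":
        y = targets.astype(int)
        n = len(y)
        p = np.clip(out, _PROB_FLOOR, 1.0)
        loss = float(-np.mean(np.log(p[np.arange(n), y])))
        onehot = np.zeros_like(out)
        onehot[np.arange(n), y] = 1.0
        delta = (out - onehot) / n  # softmax + CE shortcut
        return loss, delta
    mask = np.isfinite(targets)
    n_obs = int(mask.sum())
    if n_obs == 0:
        raise ValueError("no observed regression targets")
    resid = np.where(mask, out - np.where(mask, targets, 0.0), 0.0)
    loss = float(np.sum(resid**2) / n_obs)
    delta = 2.0 * resid / n_obs
    return loss, delta


def penalized_loss(theta: np.ndarray, X: np.ndarray, targets: np.ndarray, arch: NetArchitecture) -> float:
    """(1 - gamma) * data term + gamma * mean squared parameter value.

    The data term is the mean binary cross-entropy (classifier; predicted
    probabilities clamped at 1e-12) or the mean squared error over observed
    targets (regressor; missing targets excluded).
    """
    out, _, _ = _forward_full(theta, X, arch)
    data, _ = _data_term_and_delta(out, targets, arch)
    penalty = float(np.mean(theta**2))
    return (1.0 - arch.gamma) * data + arch.gamma * penalty


def _loss_and_grad(theta: np.ndarray, X: np.ndarray, targets: np.ndarray, arch: NetArchitecture):
    out, activations, layers = _forward_full(theta, X, arch)
    data, delta = _data_term_and_delta(out, targets, arch)
    grads: list[np.ndarray] = []
    for li in range(len(layers) - 1, -1, -1):
        W, _ = layers[li]
        a_prev = activations[li]
        gW = a_prev.T @ delta
        gb = delta.sum(axis=0)
        grads.append(gb)
        grads.append(gW.ravel())
        if li > 0:
            delta = (delta @ W.T) * (1.0 - a_prev**2)  # tanh'
    grad_data = np.concatenate(grads[::-1])
    loss = (1.0 - arch.gamma) * data + arch.gamma * float(np.mean(theta**2))
    grad = (1.0 - arch.gamma) * grad_data + arch.gamma * 2.0 * theta / theta.size
    return loss, grad


def _output_jacobian(theta: np.ndarray, X: np.ndarray, arch: NetArchitecture) -> np.ndarray:
    """Jacobian of the (linear) network outputs w.r.t. theta, by backprop.

    Returns an (n_samples * n_outputs, n_params) array whose row order
    matches ``outputs.ravel()``.  Only valid for regressor outputs.
    """
    out, activations, layers = _forward_full(theta, X, arch)
    n, n_out = out.shape
    # delta[s, o, j]: d out_so / d preactivation_j of the current layer
    delta = np.broadcast_to(np.eye(n_out), (n, n_out, n_out)).copy()
    blocks: list[np.ndarray] = []
    for li in range(len(layers) - 1, -1, -1):
        W, _ = layers[li]
        a_prev = activations[li]
        gW = np.einsum("si,soj->soij", a_prev, delta).reshape(n, n_out, -1)
        gb = delta
        blocks.append(gb.reshape(n * n_out, -1))
        blocks.append(gW.reshape(n * n_out, -1))
        if li > 0:
            delta = np.einsum("soj,ij->soi", delta, W) * (1.0 - a_prev**2)[:, None, :]
    return np.hstack(blocks[::-1])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedNet:
    """A fitted network: architecture, flat parameter vector, training report.

    ``input_mean``/``input_scale`` hold the training-set standardization
    applied to inputs before the first layer (identity when None).
    """

    architecture: NetArchitecture
    params: np.ndarray
    report: dict = field(default_factory=dict)
    seed: int = 0
    input_mean: np.ndarray | None = None
    input_scale: np.ndarray | None = None

    def predict_proba(self, X) -> np.ndarray:
        if self.architecture.output != "classifier":
            raise ValueError("predict_proba is for classifiers")
        return forward(self, X)

    def predict(self, X) -> np.ndarray:
        out = forward(self, X)
        if self.architecture.output == "classifier":
            return out.argmax(axis=1)
        return out


def _split_indices(n: int, val_frac: float, test_frac: float, rng: np.random.Generator):
    order = rng.permutation(n)
    n_val = int(round(val_frac * n))
    n_test = int(round(test_frac * n))
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError("training split is empty; reduce val/test fractions")
    return order[:n_train], order[n_train : n_train + n_val], order[n_train + n_val :]


def train_network(
    X,
    targets,
    arch: NetArchitecture,
    optimizer: str | None = None,
    seed: int = 0,
    val_frac: float = 0.15,
    test_frac: float = 0.15,
    patience: int = 5,
    max_rounds: int = 40,
    iters_per_round: int = 20,
    max_rounds_lm: int | None = 8,
    lm_nfev_per_round: int = 25,
) -> TrainedNet:
    """Full-batch training on the penalized loss with early stopping.

    Inputs are standardized to the training split's per-column mean and
    standard deviation (zero-variance columns untouched); the fitted
    statistics travel with the returned network, so callers always pass
    raw-scale inputs.

    The sample set is split 70/15/15 into train/validation/test; training
    proceeds in short optimizer rounds and stops when the validation loss
    has not improved for ``patience`` rounds (best parameters restored).
    ``optimizer`` is ``"scg"`` (conjugate gradient, classifier default) or
    ``"lm"`` (Levenberg–Marquardt with finite-difference Jacobian, regressor
    default; falls back to conjugate gradient for large parameter counts).
    Deterministic under a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if optimizer is None:
        optimizer = "scg" if arch.output == "classifier" else "lm"
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    tr, va, te = _split_indices(n, val_frac, test_frac, rng)
    mu = X[tr].mean(axis=0)
    sc = X[tr].std(axis=0)
    sc = np.where(sc > 0, sc, 1.0)
    X = (X - mu) / sc
    theta = init_params(arch, rng)

    used = optimizer
    if optimizer == "lm" and (arch.n_params > _LM_MAX_PARAMS or arch.output == "classifier"):
        used = "scg"  # FD Jacobian impractical / CE not a least-squares loss

    def val_loss(th: np.ndarray) -> float:
        if len(va) == 0:
            return penalized_loss(th, X[tr], targets[tr], arch)
        return penalized_loss(th, X[va], targets[va], arch)

    Xtr, Ttr = X[tr], targets[tr]
    loss_trace: list[float] = []
    val_trace: list[float] = []
    best_theta, best_val = theta.copy(), val_loss(theta)
    stall = 0

    if used == "lm":
        gamma = arch.gamma
        mask = np.isfinite(Ttr)
        n_obs = int(mask.sum())
        w_data = np.sqrt(max(1.0 - gamma, 0.0) / max(n_obs, 1))
        w_pen = np.sqrt(gamma / arch.n_params)

        def residuals(th: np.ndarray) -> np.ndarray:
            out, _, _ = _forward_full(th, Xtr, arch)
            r = (out - np.where(mask, Ttr, 0.0))[mask]
            return np.concatenate([w_data * r, w_pen * th])

        def jac(th: np.ndarray) -> np.ndarray:
            J = _output_jacobian(th, Xtr, arch)[mask.ravel()]
            return np.vstack([w_data * J, w_pen * np.eye(arch.n_params)])

        lm_rounds = max_rounds if max_rounds_lm is None else max_rounds_lm
        for _ in range(lm_rounds):
            res = least_squares(
                residuals, theta, jac=jac, method="lm", max_nfev=lm_nfev_per_round
            )
            theta = res.x
            loss_trace.append(penalized_loss(theta, Xtr, Ttr, arch))
            v = val_loss(theta)
            val_trace.append(v)
            if v < best_val - 1e-12:
                best_val, best_theta, stall = v, theta.copy(), 0
            else:
                stall += 1
            if stall >= patience or res.status != 0:
                break  # patience exhausted, or LM converged by tolerance
    else:
        for _ in range(max_rounds):
            res = minimize(
                _loss_and_grad,
                theta,
                args=(Xtr, Ttr, arch),
                method="CG",
                jac=True,
                options={"maxiter": iters_per_round},
            )
            theta = res.x
            loss_trace.append(float(res.fun))
            v = val_loss(theta)
            val_trace.append(v)
            if not np.isfinite(res.fun):
                raise FloatingPointError(f"training diverged; loss trace {loss_trace}")
            if v < best_val - 1e-12:
                best_val, best_theta, stall = v, theta.copy(), 0
            else:
                stall += 1
            if stall >= patience:
                break
            if res.success and len(loss_trace) > 1 and abs(loss_trace[-1] - loss_trace[-2]) < 1e-12:
                break

    report = {
        "optimizer": used,
        "requested_optimizer": optimizer,
        "loss_trace": loss_trace,
        "val_trace": val_trace,
        "rounds": len(loss_trace),
        "converged": stall < patience,
        "train_idx": tr.tolist(),
        "val_idx": va.tolist(),
        "test_idx": te.tolist(),
    }
    return TrainedNet(
        architecture=arch, params=best_theta, report=report, seed=seed,
        input_mean=mu, input_scale=sc,
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Per-fold held-out losses/metrics and their mean ± sd."""

    fold_assignments: np.ndarray
    per_fold: list[dict]
    aggregate: dict

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_fold)
        df.index.name = "fold"
        return df


def cross_validate(
    X,
    targets,
    arch: NetArchitecture,
    n_folds: int,
    seed: int = 0,
    optimizer: str | None = None,
    **train_kwargs,
) -> CVReport:
    """k-fold cross-validation: stratified for classifiers, plain otherwise.

    Fold models train on the whole training fold for a fixed budget (no
    inner validation/test carve-out — the held-out fold is the validation);
    pass ``val_frac``/``test_frac`` explicitly to override.
    """
    train_kwargs.setdefault("val_frac", 0.0)
    train_kwargs.setdefault("test_frac", 0.0)
    train_kwargs.setdefault("patience", train_kwargs.get("max_rounds", 40))
    X = np.asarray(X, dtype=float)
    targets = np.asarray(targets, dtype=float)
    n = X.shape[0]
    if not 2 <= n_folds <= n:
        raise ValueError(f"n_folds must lie in [2, {n}]")
    if arch.output == "classifier":
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, targets.astype(int))
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X)

    assignments = np.empty(n, dtype=int)
    per_fold: list[dict] = []
    for fold, (tr, te) in enumerate(split_iter):
        assignments[te] = fold
        if arch.output == "classifier":
            if len(np.unique(targets[tr].astype(int))) < 2 or len(np.unique(targets[te].astype(int))) < 2:
                raise ValueError(
                    f"fold {fold} contains a single class; use fewer folds"
                )
        net = train_network(
            X[tr], targets[tr], arch, optimizer=optimizer, seed=seed + fold, **train_kwargs
        )
        entry: dict = {"fold": fold, "loss": penalized_loss(net.params, X[te], targets[te], arch)}
        out = forward(net, X[te])
        if arch.output == "classifier":
            pred = out.argmax(axis=1)
            entry["accuracy"] = float(np.mean(pred == targets[te].astype(int)))
        else:
            t = targets[te]
            mask = np.isfinite(t)
            entry["mse"] = float(np.mean((out[mask] - t[mask]) ** 2))
            rs = []
            for j in range(out.shape[1]):
                m = mask[:, j]
                if m.sum() >= 2 and np.std(t[m, j]) > 0 and np.std(out[m, j]) > 0:
                    rs.append(pearsonr(t[m, j], out[m, j]).statistic)
            entry["mean_pearson_r"] = float(np.mean(rs)) if rs else float("nan")
        per_fold.append(entry)
    keys = [k for k in per_fold[0] if k != "fold"]
    aggregate = {}
    for k in keys:
        vals = np.array([f[k] for f in per_fold], dtype=float)
        aggregate[f"{k}_mean"] = float(np.nanmean(vals))
        aggregate[f"{k}_sd"] = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0
    return CVReport(fold_assignments=assignments, per_fold=per_fold, aggregate=aggregate)


# ---------------------------------------------------------------------------
# Bayesian hyperparameter optimization
# ---------------------------------------------------------------------------

def bayesopt_minimize(
    func: Callable[[dict], float],
    space: Mapping[str, tuple],
    n_iter: int,
    seed: int = 0,
    n_init: int = 5,
) -> tuple[dict, list[tuple[dict, float]]]:
    """Minimize a black-box function with a GP surrogate and EI acquisition.

    ``space`` maps a name to ``("float", lo, hi)`` or ``("int", lo, hi)``.
    A Latin-hypercube design seeds the surrogate; each subsequent point
    maximizes expected improvement over random candidates.  Returns the
    incumbent (lowest observed score) and the full (params, score) trace.
    """
    names = list(space)
    kinds = {k: space[k][0] for k in names}
    lo = np.array([space[k][1] for k in names], dtype=float)
    hi = np.array([space[k][2] for k in names], dtype=float)
    d = len(names)

    def decode(u: np.ndarray) -> dict:
        x = lo + u * (hi - lo)
        out = {}
        for i, k in enumerate(names):
            out[k] = int(round(x[i])) if kinds[k] == "int" else float(x[i])
        return out

    rng = np.random.default_rng(seed)
    if all(k == "int" for k in kinds.values()):
        # enumerate small all-integer grids outright when they fit the design
        sizes = [int(hi[i] - lo[i]) + 1 for i in range(d)]
        grid_total = int(np.prod(sizes))
        if grid_total <= n_init:
            mesh = np.meshgrid(*[np.arange(s) for s in sizes], indexing="ij")
            pts = np.stack([m.ravel() for m in mesh], axis=1).astype(float)
            U = list(pts / np.maximum(np.array(sizes) - 1.0, 1.0))
            n_init = len(U)
        else:
            U = None
    else:
        U = None
    if U is None:
        sampler = LatinHypercube(d=d, seed=rng.integers(0, 2**31 - 1))
        U = list(sampler.random(n=n_init))
    if n_iter < n_init:
        raise ValueError(f"n_iter={n_iter} is smaller than the initial design ({n_init})")
    trace: list[tuple[dict, float]] = []
    scores: list[float] = []
    for u in U:
        params = decode(np.asarray(u))
        s = float(func(params))
        trace.append((params, s))
        scores.append(s)

    kernel = Matern(nu=2.5, length_scale=np.full(d, 0.3)) + WhiteKernel(1e-6, (1e-10, 1e-1))
    for _ in range(n_iter - n_init):
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.asarray(U), np.asarray(scores))
        best = min(scores)
        cand = rng.random((512, d))
        mu, sd = gp.predict(cand, return_std=True)
        sd = np.maximum(sd, 1e-12)
        z = (best - mu) / sd
        ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
        u_next = cand[int(np.argmax(ei))]
        params = decode(u_next)
        s = float(func(params))
        U.append(u_next)
        trace.append((params, s))
        scores.append(s)
    best_idx = int(np.argmin(scores))
    return trace[best_idx][0], trace


def bayesopt_tune(
    X,
    targets,
    space: Mapping[str, tuple],
    n_iter: int,
    n_folds: int,
    seed: int = 0,
    base_arch: NetArchitecture | None = None,
    optimizer: str | None = None,
    n_init: int = 5,
    **train_kwargs,
) -> tuple[dict, list[tuple[dict, float]]]:
    """Tune gamma and hidden-layer sizes against the cross-validated loss.

    Recognised space keys: ``gamma`` (float), ``hidden_nodes`` (int, applied
    to every hidden layer), ``n_layers`` (int).  Any other key is rejected.
    """
    X = np.asarray(X, dtype=float)
    targets = np.asarray(targets, dtype=float)
    known = {"gamma", "hidden_nodes", "n_layers"}
    unknown = set(space) - known
    if unknown:
        raise ValueError(f"unknown hyperparameters in space: {sorted(unknown)}")
    if base_arch is None:
        base_arch = NetArchitecture(n_inputs=X.shape[1])

    def objective(params: dict) -> float:
        nodes = params.get("hidden_nodes", base_arch.hidden_layers[0])
        n_layers = params.get("n_layers", len(base_arch.hidden_layers))
        arch = NetArchitecture(
            n_inputs=base_arch.n_inputs,
            hidden_layers=[nodes] * n_layers,
            output=base_arch.output,
            n_outputs=base_arch.n_outputs,
            gamma=params.get("gamma", base_arch.gamma),
        )
        report = cross_validate(
            X, targets, arch, n_folds=n_folds, seed=seed, optimizer=optimizer, **train_kwargs
        )
        return report.aggregate["loss_mean"]

    return bayesopt_minimize(objective, space, n_iter=n_iter, seed=seed, n_init=n_init)
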