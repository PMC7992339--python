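"""Model/Results front-end over the network training layer.

`SurvivalModel` and `DrugResponseModel` are built from an integrated
feature matrix plus targets; ``fit()`` returns a results object carrying
the trained network, held-out diagnostics and a ``summary()`` table, with
plotting helpers attached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evalmetrics
from .nets import CVReport, NetArchitecture, TrainedNet, cross_validate, forward, train_network


@dataclass
class SurvivalResults:
    """Fitted survival classifier with its held-out diagnostics."""

    model: "SurvivalModel"
    net: TrainedNet
    cv_report: CVReport | None
    metrics: dict
    auroc: float

    def predict(self, X) -> np.ndarray:
        return self.net.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X) -> np.ndarray:
        return self.net.predict_proba(np.asarray(X, dtype=float))

    def summary(self) -> pd.DataFrame:
        rows = [{"metric": k, "value": v} for k, v in self.metrics.items()]
        rows.append({"metric": "auroc", "value": self.auroc})
        if self.cv_report is not None:
            for k, v in self.cv_report.aggregate.items():
                rows.append({"metric": f"cv_{k}", "value": v})
        return pd.DataFrame(rows)

    def plot_roc(self, ax=None):
        """ROC curve of the held-out test scores."""
        import matplotlib.pyplot as plt

        te = self.net.report["test_idx"]
        scores = self.predict_proba(self.model.X[te])[:, 1]
        y = self.model.y[te]
        order = np.argsort(-scores)
        tps = np.cumsum(y[order] == 1)
        fps = np.cumsum(y[order] == 0)
        tpr = tps / max(tps[-1], 1)
        fpr = fps / max(fps[-1], 1)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.r_[0, fpr], np.r_[0, tpr])
        ax.plot([0, 1], [0, 1], ls="--", c="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        return ax


class SurvivalModel:
    """Binary risk classifier on an integrated multi-omics matrix.

    Parameters
    ----------
    X : array-like or DataFrame, samples x features
    y : binary vector (1 = high risk)
    hidden_layers, gamma : network architecture knobs.
    """

    def __init__(self, X, y, hidden_layers=(7, 7), gamma: float = 0.1):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y).astype(int)
        self.feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        self.arch = NetArchitecture(
            n_inputs=self.X.shape[1], hidden_layers=list(hidden_layers), output="classifier", gamma=gamma
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str, **kwargs) -> "SurvivalModel":
        y = df[label_col]
        X = df.drop(columns=[label_col])
        return cls(X, y, **kwargs)

    def fit(self, optimizer: str = "scg", seed: int = 0, cv_folds: int | None = None, **train_kwargs) -> SurvivalResults:
        cv = (
            cross_validate(self.X, self.y, self.arch, n_folds=cv_folds, seed=seed, optimizer=optimizer, **train_kwargs)
            if cv_folds
            else None
        )
        net = train_network(self.X, self.y, self.arch, optimizer=optimizer, seed=seed, **train_kwargs)
        te = net.report["test_idx"] or net.report["val_idx"] or net.report["train_idx"]
        proba = forward(net, self.X[te])
        pred = proba.argmax(axis=1)
        cm = evalmetrics.ConfusionMatrix.from_labels(self.y[te], pred, positive=1)
        metrics = evalmetrics.classification_metrics(cm)
        try:
            auc = evalmetrics.auroc(proba[:, 1], self.y[te] == 1)
        except ValueError:
            auc = float("nan")
        return SurvivalResults(model=self, net=net, cv_report=cv, metrics=metrics, auroc=auc)


@dataclass
class DrugResponseResults:
    """Fitted multi-drug IC50 regressor with per-drug diagnostics."""

    model: "DrugResponseModel"
    net: TrainedNet
    cv_report: CVReport | None
    per_drug: pd.DataFrame  # held-out mse / pearson_r per drug

    def predict(self, X) -> pd.DataFrame:
        out = forward(self.net, np.asarray(X, dtype=float))
        return pd.DataFrame(out, columns=self.model.drug_ids)

    def summary(self) -> pd.DataFrame:
        return self.per_drug

    def plot_fit(self, drug_id: str, ax=None):
        """Held-out predicted vs observed IC50 for one drug."""
        import matplotlib.pyplot as plt

        te = self.net.report["test_idx"]
        j = self.model.drug_ids.index(drug_id)
        pred = forward(self.net, self.model.X[te])[:, j]
        obs = self.model.Y[te, j]
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(obs, pred, s=12)
        ax.set_xlabel("observed IC50 (z)")
        ax.set_ylabel("predicted IC50 (z)")
        ax.set_title(drug_id)
        return ax


class DrugResponseModel:
    """Multi-output IC50 regressor on an integrated cell-line matrix."""

    def __init__(self, X, Y, hidden_layers=(11, 11), gamma: float = 0.3743):
        self.X = np.asarray(X, dtype=float)
        if isinstance(Y, pd.DataFrame):
            self.drug_ids = list(Y.columns)
            self.Y = Y.to_numpy(dtype=float)
        else:
            self.Y = np.asarray(Y, dtype=float)
            self.drug_ids = [f"drug_{j}" for j in range(self.Y.shape[1])]
        self.arch = NetArchitecture(
            n_inputs=self.X.shape[1],
            hidden_layers=list(hidden_layers),
            output="regressor",
            n_outputs=self.Y.shape[1],
            gamma=gamma,
        )

    def fit(self, optimizer: str = "lm", seed: int = 0, cv_folds: int | None = None, **train_kwargs) -> DrugResponseResults:
        cv = (
            cross_validate(self.X, self.Y, self.arch, n_folds=cv_folds, seed=seed, optimizer=optimizer, **train_kwargs)
            if cv_folds
            else None
        )
        net = train_network(self.X, self.Y, self.arch, optimizer=optimizer, seed=seed, **train_kwargs)
        te = net.report["test_idx"] or net.report["val_idx"] or net.report["train_idx"]
        pred = forward(net, self.X[te])
        rows = []
        for j, drug in enumerate(self.drug_ids):
            obs = self.Y[te, j]
            ok = np.isfinite(obs)
            if ok.sum() >= 2 and np.std(obs[ok]) > 0 and np.std(pred[ok, j]) > 0:
                m = evalmetrics.regression_metrics(obs[ok], pred[ok, j])
            else:
                m = {"mse": float("nan"), "pearson_r": float("nan"), "r_squared": float("nan")}
            rows.append({"drug_id": drug, **m})
        return DrugResponseResults(
            model=self, net=net, cv_report=cv, per_drug=pd.DataFrame(rows).set_index("drug_id")
        )
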