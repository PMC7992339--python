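"""End-to-end survival and drug-response pipelines driven by a YAML config.

Both pipelines share the preprocessing backbone — read (or synthesize),
missingness-filter, kNN-impute, scale, sample-align — then run supervised
NCA feature selection per omics layer, concatenate the selected blocks
(late integration), and train the task network.  The survival pipeline adds
SMOTE class balancing and 10-fold cross-validation; the drug pipeline adds
per-drug IC50 binarization (K-means and waterfall), a cross-validated
call-accuracy filter on drugs, and 5-fold cross-validation.

Every stage writes to a run log with a samples_in/samples_out/dropped
accounting line, and every artifact is stamped with the config hash and
seed, so reruns with the same config are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import KFold

from . import omics_io, response, synthdata
from .evalmetrics import ConfusionMatrix, classification_metrics
from .models import DrugResponseModel, SurvivalModel
from .ncfs import NCFSParams, ncfs_fit
from .nets import NetArchitecture, bayesopt_tune, forward, late_integrate, train_network
from .sampling import SmoteParams, smote


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def validate_config(config: dict, task: str) -> None:
    """Reject an invalid config before any compute."""
    if config.get("task") != task:
        raise ValueError(f"config task {config.get('task')!r} does not match {task!r}")
    if "seed" not in config:
        raise ValueError("config must declare a seed")
    if "synth" not in config and "layers" not in config:
        raise ValueError("config must declare either a 'synth' section or layer paths")
    if task == "survival" and "clinical" not in config:
        raise ValueError("survival config must declare a 'clinical' covariate spec")


class RunLog:
    def __init__(self) -> None:
        self.lines: list[str] = []

    def log(self, msg: str) -> None:
        self.lines.append(msg)

    def account(self, stage: str, n_in: int, n_out: int) -> None:
        dropped = n_in - n_out
        assert n_in == n_out + dropped
        self.log(f"{stage}: samples_in={n_in} samples_out={n_out} dropped={dropped}")

    def write(self, path) -> None:
        Path(path).write_text("\n".join(self.lines) + "\n")


def _load_or_synthesize(config: dict, log: RunLog):
    """Return (dataset, drug table or None, labels or None, truth or None)."""
    if "synth" in config:
        s = dict(config["synth"])
        want_drugs = s.pop("with_drugs", config["task"] == "drug_response")
        cfg = synthdata.SyntheticConfig(seed=config["seed"], **s)
        dataset, truth = synthdata.generate_multiomics(cfg)
        labels = synthdata.generate_survival_labels(dataset, truth, cfg)
        drugs = synthdata.generate_drug_response(dataset, truth, cfg) if want_drugs else None
        log.log(f"synthesized dataset: n={cfg.n_samples}, layers={[t for t, _ in cfg.omics_spec]}")
        return dataset, drugs, labels, truth
    layers = {
        name: omics_io.read_omics_matrix(path, name)
        for name, path in config["layers"].items()
    }
    clinical = omics_io.read_table(config["clinical_path"]) if "clinical_path" in config else None
    labels = None
    if "labels_path" in config:
        labels = omics_io.read_table(config["labels_path"]).iloc[:, 0]
    drugs = None
    if "drug_table_path" in config:
        drugs = omics_io.DrugResponseTable(omics_io.read_table(config["drug_table_path"]))
    dataset = omics_io.MultiOmicsDataset(layers=layers, clinical=clinical, labels=labels)
    return dataset, drugs, labels, None


def _preprocess_layers(dataset, labels, config: dict, log: RunLog):
    """Missingness filter, kNN imputation and scaling per layer, then alignment."""
    max_frac = config.get("max_missing_frac", 0.2)
    k = config.get("impute_k", 10)
    processed = {}
    for name, layer in dataset.layers.items():
        n_in = layer.shape[0]
        filt = omics_io.filter_missing(layer, max_frac)
        log.account(f"filter_missing[{name}]", n_in, filt.shape[0])
        imp = omics_io.knn_impute(filt, min(k, filt.shape[1] - 1))
        processed[name] = omics_io.scale_matrix(imp)
    aligned = omics_io.align_samples(processed, dataset.clinical, labels)
    log.account("align_samples", max(m.shape[0] for m in dataset.layers.values()),
                len(aligned.sample_ids))
    return aligned


def _select_per_layer(aligned, y, task: str, config: dict, log: RunLog) -> dict:
    """NCA feature selection on each layer; returns layer -> index list."""
    ncfs_cfg = config.get("ncfs", {})
    rule = ncfs_cfg.get("rule", "weight_above")
    k = ncfs_cfg.get("top_k")
    tau = ncfs_cfg.get("tau", 0.1)
    selections, weights = {}, {}
    for name, layer in aligned.layers.items():
        params = NCFSParams(
            sigma=ncfs_cfg.get("sigma"),
            lam=ncfs_cfg.get("lam"),
            max_iter=ncfs_cfg.get("max_iter", 50),
            task="classification" if task == "survival" else "regression",
            seed=config["seed"],
        )
        X = layer.values
        if task == "survival":
            fw = ncfs_fit(X, y, params)
        else:
            # multi-drug target: average NCFS weights over per-drug regressions
            w_sum = None
            for j in range(y.shape[1]):
                col = y[:, j]
                ok = np.isfinite(col)
                fw_j = ncfs_fit(X.to_numpy()[ok], col[ok], params)
                w_sum = fw_j.w if w_sum is None else w_sum + fw_j.w
            fw = fw_j
            fw.w = w_sum / y.shape[1]
            fw.feature_ids = list(X.columns)
        selections[name] = fw.select(rule=rule, k=k, tau=tau)
        weights[name] = fw
        log.log(f"ncfs[{name}]: selected {len(selections[name])}/{layer.shape[1]} features")
    return selections, weights


def _maybe_tune(X, targets, arch, config: dict, log: RunLog) -> NetArchitecture:
    tuning = config.get("tuning")
    if not tuning or not tuning.get("enabled", True):
        return arch
    space = {k: tuple(v) for k, v in tuning["space"].items()}
    best, trace = bayesopt_tune(
        X,
        targets,
        space,
        n_iter=tuning.get("n_iter", 15),
        n_folds=tuning.get("n_folds", 3),
        seed=config["seed"],
        base_arch=arch,
        max_rounds=tuning.get("max_rounds", 10),
    )
    log.log(f"bayesopt incumbent: {best} after {len(trace)} evaluations")
    nodes = best.get("hidden_nodes", arch.hidden_layers[0])
    n_layers = best.get("n_layers", len(arch.hidden_layers))
    return NetArchitecture(
        n_inputs=arch.n_inputs,
        hidden_layers=[nodes] * n_layers,
        output=arch.output,
        n_outputs=arch.n_outputs,
        gamma=best.get("gamma", arch.gamma),
    )


def run_survival_pipeline(config: dict, outdir) -> dict:
    """Full survival pipeline; returns the artifact bundle as a dict."""
    validate_config(config, "survival")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    log.log(f"survival pipeline, seed={config['seed']}, config_hash={_config_hash(config)}")

    dataset, _, labels, truth = _load_or_synthesize(config, log)
    aligned = _preprocess_layers(dataset, labels, config, log)
    y = (aligned.labels == "high_risk").to_numpy().astype(int)

    selections, weights = _select_per_layer(aligned, y, "survival", config, log)
    for name, fw in weights.items():
        fw.to_tsv(outdir / f"selected_features_{name}.tsv")

    integrated = late_integrate(aligned, selections, config.get("clinical"))
    n_before = integrated.shape[0]
    Xb, yb = smote(
        integrated.to_numpy(),
        y,
        SmoteParams(**config.get("smote", {}), seed=config["seed"]),
    )
    log.log(f"smote: {n_before} -> {len(yb)} samples")

    arch = NetArchitecture(
        n_inputs=Xb.shape[1],
        hidden_layers=config.get("hidden_layers", [7, 7]),
        output="classifier",
        gamma=config.get("gamma", 0.1),
    )
    arch = _maybe_tune(Xb, yb, arch, config, log)

    model = SurvivalModel(pd.DataFrame(Xb, columns=integrated.columns), yb,
                         hidden_layers=arch.hidden_layers, gamma=arch.gamma)
    results = model.fit(seed=config["seed"], cv_folds=config.get("cv_folds", 10),
                        max_rounds=config.get("max_rounds", 40))

    results.summary().to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    results.cv_report.summary().to_csv(outdir / "cv_report.tsv", sep="\t", index=False)
    _save_net(results.net, outdir)
    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump({**config, "config_hash": _config_hash(config)}, fh)
    log.write(outdir / "run_log.txt")
    return {
        "integrated": integrated,
        "selections": selections,
        "results": results,
        "cv_accuracy": results.cv_report.aggregate["accuracy_mean"],
        "truth": truth,
        "outdir": outdir,
    }


def cv_predictions(X: np.ndarray, Y: np.ndarray, arch: NetArchitecture, n_folds: int, seed: int, **train_kwargs) -> np.ndarray:
    """Out-of-fold predictions for every sample (regression)."""
    train_kwargs.setdefault("val_frac", 0.0)
    train_kwargs.setdefault("test_frac", 0.0)
    train_kwargs.setdefault("patience", train_kwargs.get("max_rounds", 40))
    pred = np.full(Y.shape, np.nan)
    for fold, (tr, te) in enumerate(KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(X)):
        net = train_network(X[tr], Y[tr], arch, seed=seed + fold, **train_kwargs)
        pred[te] = forward(net, X[te])
    return pred


def filter_drugs_by_accuracy(
    cv_calls: pd.DataFrame, truth_calls: pd.DataFrame, min_accuracy: float = 0.5
) -> tuple[list[str], pd.DataFrame]:
    """Retain drugs whose cross-validated call accuracy is >= ``min_accuracy``.

    Accuracy per drug is the agreement between out-of-fold sensitive/resistant
    calls and the calls on observed IC50, over non-missing pairs.
    """
    rows = []
    for drug in cv_calls.columns:
        a = cv_calls[drug]
        b = truth_calls[drug]
        ok = a.notna() & b.notna()
        acc = float((a[ok] == b[ok]).mean()) if ok.any() else float("nan")
        rows.append({"drug_id": drug, "accuracy": acc, "retained": acc >= min_accuracy})
    report = pd.DataFrame(rows).set_index("drug_id")
    retained = list(report.index[report["retained"]])
    if not retained:
        raise ValueError("no drug passes the accuracy filter")
    return retained, report


def run_drug_pipeline(config: dict, outdir) -> dict:
    """Full drug-response pipeline; returns the artifact bundle as a dict."""
    validate_config(config, "drug_response")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    log.log(f"drug pipeline, seed={config['seed']}, config_hash={_config_hash(config)}")

    dataset, drugs, _, truth = _load_or_synthesize(config, log)
    if drugs is None:
        raise ValueError("drug_response task requires a drug table")
    n_in = len(drugs.cell_line_ids)
    dataset, drugs = omics_io.filter_cell_lines(
        dataset, drugs,
        min_drug_frac=config.get("min_drug_frac", 0.8),
        max_missing_frac=config.get("max_missing_frac", 0.2),
        impute_k=config.get("impute_k", 10),
    )
    log.account("filter_cell_lines", n_in, len(drugs.cell_line_ids))
    aligned = _preprocess_layers(dataset, None, config, log)
    ic50 = drugs.ic50.loc[aligned.sample_ids]
    Y = ic50.to_numpy(dtype=float)

    selections, weights = _select_per_layer(aligned, Y, "drug_response", config, log)
    for name, fw in weights.items():
        fw.to_tsv(outdir / f"selected_features_{name}.tsv")

    integrated = late_integrate(aligned, selections, config.get("clinical"))
    X = integrated.to_numpy(dtype=float)

    arch = NetArchitecture(
        n_inputs=X.shape[1],
        hidden_layers=config.get("hidden_layers", [11, 11]),
        output="regressor",
        n_outputs=Y.shape[1],
        gamma=config.get("gamma", 0.3743),
    )
    arch = _maybe_tune(X, Y, arch, config, log)

    # per-drug thresholds on the observed IC50 distributions
    km_records, wf_records = [], []
    for drug in ic50.columns:
        rec, _ = response.kmeans_binarize(ic50[drug].to_numpy(), drug_id=drug, seed=config["seed"])
        km_records.append(rec)
        wf_records.append(response.waterfall_threshold(ic50[drug].to_numpy(), drug_id=drug))
    response.thresholds_to_tsv(km_records, outdir / "thresholds_kmeans.tsv")
    response.thresholds_to_tsv(wf_records, outdir / "thresholds_waterfall.tsv")

    # accuracy filter on cross-validated binarized calls
    n_folds = config.get("cv_folds", 5)
    oof = cv_predictions(X, Y, arch, n_folds=n_folds, seed=config["seed"],
                         max_rounds=config.get("max_rounds", 20))
    oof_df = pd.DataFrame(oof, index=ic50.index, columns=ic50.columns)
    cv_calls = response.binarize_predictions(oof_df, km_records)
    truth_calls = response.binarize_predictions(ic50, km_records)
    retained, acc_report = filter_drugs_by_accuracy(
        cv_calls, truth_calls, config.get("min_call_accuracy", 0.5)
    )
    acc_report.to_csv(outdir / "drug_accuracy_filter.tsv", sep="\t")
    log.log(f"accuracy filter retained {len(retained)}/{ic50.shape[1]} drugs")

    model = DrugResponseModel(
        pd.DataFrame(X, index=ic50.index, columns=integrated.columns),
        ic50[retained],
        hidden_layers=arch.hidden_layers,
        gamma=arch.gamma,
    )
    results = model.fit(seed=config["seed"], cv_folds=n_folds,
                        max_rounds=config.get("max_rounds", 20))
    results.summary().to_csv(outdir / "per_drug_metrics.tsv", sep="\t")
    _save_net(results.net, outdir)
    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump({**config, "config_hash": _config_hash(config)}, fh)
    log.write(outdir / "run_log.txt")
    return {
        "integrated": integrated,
        "selections": selections,
        "results": results,
        "kmeans_thresholds": km_records,
        "waterfall_thresholds": wf_records,
        "retained_drugs": retained,
        "accuracy_report": acc_report,
        "oof_predictions": oof_df,
        "cv_report": results.cv_report,
        "truth": truth,
        "outdir": outdir,
    }


def _save_net(net, outdir: Path) -> None:
    """Text archive: architecture as YAML, flat parameter vector as TSV."""
    arch = net.architecture
    with open(outdir / "model_arch.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "n_inputs": arch.n_inputs,
                "hidden_layers": list(arch.hidden_layers),
                "output": arch.output,
                "n_outputs": arch.n_outputs,
                "gamma": arch.gamma,
                "seed": net.seed,
                "optimizer": net.report.get("optimizer"),
            },
            fh,
        )
    pd.Series(net.params, name="theta").to_csv(outdir / "model_weights.tsv", sep="\t")
    if net.input_mean is not None:
        pd.DataFrame({"mean": net.input_mean, "scale": net.input_scale}).to_csv(
            outdir / "model_input_scaling.tsv", sep="\t"
        )


def load_net(outdir) -> "TrainedNet":
    from .nets import TrainedNet

    outdir = Path(outdir)
    with open(outdir / "model_arch.yaml") as fh:
        meta = yaml.safe_load(fh)
    arch = NetArchitecture(
        n_inputs=meta["n_inputs"],
        hidden_layers=meta["hidden_layers"],
        output=meta["output"],
        n_outputs=meta["n_outputs"],
        gamma=meta["gamma"],
    )
    theta = pd.read_csv(outdir / "model_weights.tsv", sep="\t", index_col=0)["theta"].to_numpy()
    mean = scale = None
    scaling_path = outdir / "model_input_scaling.tsv"
    if scaling_path.exists():
        scaling = pd.read_csv(scaling_path, sep="\t", index_col=0)
        mean = scaling["mean"].to_numpy()
        scale = scaling["scale"].to_numpy()
    return TrainedNet(
        architecture=arch, params=theta, seed=meta.get("seed", 0),
        input_mean=mean, input_scale=scale,
    )
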