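"""Synthetic multi-omics datasets with planted, recoverable signal.

The generator emulates the shapes and value conventions of TCGA-style
patient omics (six layers) and GDSC-style cell-line drug-response tables:
per-layer value ranges (beta values in [0,1], binary mutations, copy-number
scores in [-1,1], standardized expression), missing-completely-at-random
entries, class-imbalanced binary survival labels, and per-drug IC50 z-scores
with a planted linear dependence on a known set of informative features.

Every layer is derived from a latent standardized Gaussian matrix Z; the
native-scale values are monotone transforms of Z, so the planted signal
survives the preprocessing pipeline (z-scoring, log-transforms) and is
recoverable by supervised feature selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .omics_io import OMICS_TYPES, DrugResponseTable, MultiOmicsDataset, OmicsMatrix


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic multi-omics study.

    Defaults define the study conditions the package is tested under: a
    minority (high-risk) fraction of 0.3, in the range of observed adverse-
    outcome rates in breast-cancer cohorts and large enough that a planted
    signal is statistically recoverable at n ~ 200, and a residual noise
    standard deviation equal to one informative feature's effect.
    """

    n_samples: int = 200
    omics_spec: list[tuple[str, int]] = field(
        default_factory=lambda: [("mrna", 500), ("methylation", 500), ("cnv", 500)]
    )
    n_informative_per_omics: int = 10
    class_imbalance: float = 0.3
    n_drugs: int = 20
    effect_size: float = 1.0
    noise_sd: float = 1.0
    missing_frac: float = 0.0
    n_bimodal_drugs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for omics_type, n_features in self.omics_spec:
            if omics_type not in OMICS_TYPES:
                raise ValueError(f"unknown omics_type {omics_type!r} in omics_spec")
            if self.n_informative_per_omics >= n_features:
                raise ValueError(
                    f"n_informative_per_omics={self.n_informative_per_omics} must be "
                    f"< n_features={n_features} for layer {omics_type!r}"
                )
        if not 0 < self.class_imbalance <= 1:
            raise ValueError("class_imbalance must lie in (0, 1]")
        if not 0 <= self.missing_frac < 0.5:
            raise ValueError("missing_frac must lie in [0, 0.5)")
        if self.n_bimodal_drugs > self.n_drugs:
            raise ValueError("n_bimodal_drugs cannot exceed n_drugs")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset.

    ``latent`` holds the standardized Gaussian matrix each layer was derived
    from; ``native`` the complete (pre-missingness) native-scale values.
    Outcome scores are linear in the standardized native informative columns.
    """

    informative_features: dict[str, list[int]]
    survival_coefficients: np.ndarray
    drug_coefficients: pd.DataFrame
    true_labels: pd.Series | None
    true_ic50: pd.DataFrame | None
    latent: dict[str, pd.DataFrame] = field(default_factory=dict)
    native: dict[str, pd.DataFrame] = field(default_factory=dict)


def _latent_to_native(z: np.ndarray, omics_type: str, rng: np.random.Generator) -> np.ndarray:
    """Map a latent standard-normal column block onto the layer's native scale."""
    if omics_type in ("mrna", "protein"):
        return z
    if omics_type == "mirna":
        # RPM-like counts whose log2(x+1) is an affine image of z
        return np.maximum(2.0 ** (z + 5.0) - 1.0, 0.0)
    if omics_type == "methylation":
        return beta_dist.ppf(np.clip(norm.cdf(z), 1e-12, 1 - 1e-12), 2.0, 2.0)
    if omics_type == "cnv":
        return np.tanh(0.6 * z)
    if omics_type == "mutation":
        rates = rng.uniform(0.05, 0.4, size=z.shape[1])
        return (norm.cdf(z) < rates).astype(float)
    raise ValueError(f"unknown omics_type {omics_type!r}")


def _inject_mcar(df: pd.DataFrame, frac: float, rng: np.random.Generator) -> pd.DataFrame:
    if frac <= 0:
        return df
    mask = rng.random(df.shape) < frac
    out = df.astype(float).copy()
    out.values[mask] = np.nan
    return out


def generate_multiomics(config: SyntheticConfig) -> tuple[MultiOmicsDataset, SyntheticTruth]:
    """Generate an aligned multi-omics dataset plus its ground truth.

    Sample identifiers are shared across layers; each layer carries
    ``missing_frac`` MCAR missingness.  A random subset of
    ``n_informative_per_omics`` columns per layer (recorded in the returned
    truth) drives the outcome scores used by
    :func:`generate_survival_labels` and :func:`generate_drug_response`;
    the scores are linear in the standardized *native* values of those
    columns, i.e. in exactly what a model sees after preprocessing.
    """
    rng = np.random.default_rng(config.seed)
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    layers: dict[str, OmicsMatrix] = {}
    latent: dict[str, pd.DataFrame] = {}
    native_full: dict[str, pd.DataFrame] = {}
    informative: dict[str, list[int]] = {}
    for omics_type, n_features in config.omics_spec:
        z = rng.standard_normal((config.n_samples, n_features))
        features = [f"{omics_type}_f{j}" for j in range(n_features)]
        native = _latent_to_native(z, omics_type, rng)
        idx = rng.choice(n_features, size=config.n_informative_per_omics, replace=False)
        informative[omics_type] = sorted(int(i) for i in idx)
        latent[omics_type] = pd.DataFrame(z, index=samples, columns=features)
        native_full[omics_type] = pd.DataFrame(native, index=samples, columns=features)
        values = _inject_mcar(
            native_full[omics_type].copy(),
            config.missing_frac,
            rng,
        )
        layers[omics_type] = OmicsMatrix(values, omics_type)
    clinical = pd.DataFrame(
        {
            "age": rng.normal(58.0, 12.0, config.n_samples).round(1),
            "stage": rng.choice(["I", "II", "III"], config.n_samples, p=[0.3, 0.5, 0.2]),
        },
        index=samples,
    )
    n_inf_total = config.n_informative_per_omics * len(config.omics_spec)
    truth = SyntheticTruth(
        informative_features=informative,
        survival_coefficients=np.full(n_inf_total, config.effect_size),
        drug_coefficients=pd.DataFrame(),
        true_labels=None,
        true_ic50=None,
        latent=latent,
        native=native_full,
    )
    dataset = MultiOmicsDataset(layers=layers, clinical=clinical)
    return dataset, truth


def _informative_signal(truth: SyntheticTruth) -> np.ndarray:
    """Standardized native informative columns of every layer, stacked.

    Standardizing per column keeps ``effect_size`` a standardized effect
    regardless of each layer's native scale (beta values, binary calls,
    copy-number scores).
    """
    blocks = []
    for omics_type, idx in truth.informative_features.items():
        x = truth.native[omics_type].to_numpy()[:, idx]
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        blocks.append((x - mu) / sd)
    return np.hstack(blocks)


def generate_survival_labels(
    dataset: MultiOmicsDataset, truth: SyntheticTruth, config: SyntheticConfig
) -> pd.Series:
    """Threshold a noisy linear risk score into high-/low-risk labels.

    The score is ``effect_size * sum(standardized informative features) +
    N(0, noise_sd)`` — the linear predictor of a logistic risk model — and a
    sample is high-risk iff its score exceeds the analytic
    ``1 - class_imbalance`` quantile of the score's sampling distribution
    (Gaussian to excellent approximation: a sum of independent standardized
    variables plus Gaussian noise).  The realized minority
    fraction is therefore binomial around ``class_imbalance``, within ±5
    percentage points for n >= 200 with high probability.
    """
    rng = np.random.default_rng(config.seed + 1)
    z_inf = _informative_signal(truth)
    score = z_inf @ truth.survival_coefficients
    if config.noise_sd > 0:
        score = score + rng.normal(0.0, config.noise_sd, size=score.shape)
    score_sd = float(
        np.sqrt(np.sum(truth.survival_coefficients**2) + config.noise_sd**2)
    )
    if score_sd == 0:
        high = rng.random(score.shape[0]) < config.class_imbalance
    else:
        b = score_sd * norm.ppf(1.0 - config.class_imbalance)
        high = score > b
    labels = pd.Series(
        np.where(high, "high_risk", "low_risk"),
        index=dataset.sample_ids,
        name="risk",
    )
    truth.true_labels = labels
    return labels


def generate_drug_response(
    dataset: MultiOmicsDataset, truth: SyntheticTruth, config: SyntheticConfig
) -> DrugResponseTable:
    """Generate a cell-line x drug IC50 z-score table with planted linear signal.

    Each drug's IC50 is a linear function of the planted (standardized) features
    (coefficients of magnitude ``effect_size``, random sign) plus Gaussian
    noise, standardized per drug.  The first ``n_bimodal_drugs`` drugs are
    made bimodal — a ±2 shift by the sign of the linear score — which also
    yields the step/sigmoidal sorted profile waterfall analysis expects.
    """
    if config.n_drugs < 1:
        raise ValueError("n_drugs must be >= 1")
    rng = np.random.default_rng(config.seed + 2)
    z_inf = _informative_signal(truth)
    n, p = z_inf.shape
    drugs = [f"drug_{d:03d}" for d in range(config.n_drugs)]
    coefs = config.effect_size * rng.choice([-1.0, 1.0], size=(config.n_drugs, p))
    ic50 = np.empty((n, config.n_drugs))
    true_ic50 = np.empty_like(ic50)
    for d in range(config.n_drugs):
        linear = z_inf @ coefs[d]
        if d < config.n_bimodal_drugs:
            base = 2.0 * np.sign(linear) + 0.1 * linear
            noise_scale = 0.2 * config.noise_sd
        else:
            base = linear
            noise_scale = config.noise_sd
        true_ic50[:, d] = base
        noisy = base + rng.normal(0.0, noise_scale, size=n) if noise_scale > 0 else base.copy()
        sd = noisy.std(ddof=0)
        ic50[:, d] = (noisy - noisy.mean()) / (sd if sd > 0 else 1.0)
    frame = pd.DataFrame(ic50, index=dataset.sample_ids, columns=drugs)
    frame = _inject_mcar(frame, config.missing_frac, rng)
    truth.drug_coefficients = pd.DataFrame(coefs, index=drugs)
    truth.true_ic50 = pd.DataFrame(true_ic50, index=dataset.sample_ids, columns=drugs)
    return DrugResponseTable(frame)
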