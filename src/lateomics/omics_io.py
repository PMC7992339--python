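"""Reading, filtering, imputing, scaling and aligning per-omics matrices.

Matrices are stored samples x features.  Six omics layers are recognised,
each with its own value convention:

=============  =============================================  ==============
omics_type     native scale                                   values
=============  =============================================  ==============
mrna           z-scaled RSEM expression                       real
mirna          RPM (reads per million), log2-transformed       >= 0 raw,
               and z-scored by :func:`scale_matrix`            real scaled
protein        scaled RPPA abundance                          real
methylation    beta values                                    [0, 1]
mutation       binary mutation calls                          {0, 1}
cnv            GISTIC2 copy-number scores                     [-1, 1]
=============  =============================================  ==============

Missing values are ``NaN`` in memory and ``NA`` (or empty) on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

OMICS_TYPES = ("mrna", "mirna", "protein", "methylation", "mutation", "cnv")

#: layers z-scored per feature by scale_matrix; mirna is log2(x+1) first
_ZSCORE_LAYERS = {"mrna", "mirna"}


def _check_unique(ids: Sequence, kind: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()][0]
        raise ValueError(f"duplicate {kind} identifier: {dup!r}")


@dataclass
class OmicsMatrix:
    """One omics layer: a samples x features numeric grid with a type tag.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are samples, columns are features, missing entries are NaN.
    omics_type : str
        One of :data:`OMICS_TYPES`.
    scaling : str
        Free-form tag recording the scaling convention currently applied.
    """

    values: pd.DataFrame
    omics_type: str
    scaling: str = "raw"

    def __post_init__(self) -> None:
        if self.omics_type not in OMICS_TYPES:
            raise ValueError(
                f"unknown omics_type {self.omics_type!r}; expected one of {OMICS_TYPES}"
            )
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "feature")
        vals = self.values.to_numpy(dtype=float)
        if self.omics_type == "mutation":
            obs = vals[~np.isnan(vals)]
            if obs.size and not np.isin(obs, (0.0, 1.0)).all():
                bad = obs[~np.isin(obs, (0.0, 1.0))][0]
                raise ValueError(f"mutation layer contains non-binary value {bad}")
        if self.omics_type == "methylation":
            obs = vals[~np.isnan(vals)]
            if obs.size and ((obs < 0) | (obs > 1)).any():
                bad = obs[(obs < 0) | (obs > 1)][0]
                raise ValueError(f"methylation beta value {bad} outside [0, 1]")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()


@dataclass
class MultiOmicsDataset:
    """Sample-aligned collection of omics layers plus clinical covariates."""

    layers: dict[str, OmicsMatrix]
    clinical: pd.DataFrame | None = None
    labels: pd.Series | None = None

    @property
    def sample_ids(self) -> list:
        first = next(iter(self.layers.values()))
        return first.sample_ids

    def check_aligned(self) -> None:
        ref = self.sample_ids
        for name, layer in self.layers.items():
            if layer.sample_ids != ref:
                raise ValueError(f"layer {name!r} sample order differs from the others")
        if self.clinical is not None and list(self.clinical.index) != ref:
            raise ValueError("clinical table sample order differs from omics layers")
        if self.labels is not None and list(self.labels.index) != ref:
            raise ValueError("label vector sample order differs from omics layers")


@dataclass
class DrugResponseTable:
    """Cell line x drug IC50 grid on the z-score scale; NaN allowed."""

    ic50: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.ic50.index, "cell line")
        _check_unique(self.ic50.columns, "drug")

    @property
    def cell_line_ids(self) -> list:
        return list(self.ic50.index)

    @property
    def drug_ids(self) -> list:
        return list(self.ic50.columns)


def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_table(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited text table: first column = row IDs, header = column IDs."""
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path, delimiter),
        index_col=0,
        na_values=["NA"],
        keep_default_na=False,
    )
    return df


def read_omics_matrix(path, omics_type: str, delimiter: str | None = None) -> OmicsMatrix:
    """Read one omics layer from a TSV/CSV file.

    ``NA`` and empty cells become missing.  A non-numeric cell raises with its
    row/column address; duplicate identifiers raise naming the duplicate.
    """
    df = read_table(path, delimiter)
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = bad.idxmax()
                raise ValueError(
                    f"non-numeric value {df.loc[row, col]!r} at row {row!r}, "
                    f"column {col!r} in {path}"
                )
            df[col] = coerced
    return OmicsMatrix(df.astype(float), omics_type)


def write_matrix(df: pd.DataFrame, path, delimiter: str | None = None) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path, delimiter), na_rep="NA")


def write_omics_matrix(matrix: OmicsMatrix, path, delimiter: str | None = None) -> None:
    write_matrix(matrix.values, path, delimiter)


def filter_missing(matrix: OmicsMatrix, max_frac: float = 0.2) -> OmicsMatrix:
    """Drop samples, then features, with a missing fraction above ``max_frac``.

    Samples are filtered first; feature missingness is recomputed on the
    surviving samples.  Row/column order of survivors is preserved.
    """
    if not 0 <= max_frac < 1:
        raise ValueError("max_frac must lie in [0, 1)")
    df = matrix.values
    keep_samples = df.isna().mean(axis=1) <= max_frac
    if not keep_samples.any():
        raise ValueError("all samples exceed the missingness threshold")
    df = df.loc[keep_samples]
    keep_features = df.isna().mean(axis=0) <= max_frac
    df = df.loc[:, keep_features]
    return replace(matrix, values=df)


def knn_impute(matrix: OmicsMatrix, k: int = 10) -> OmicsMatrix:
    """Impute missing cells from the k nearest features.

    Follows R ``impute.knn`` semantics: for a missing cell (sample s, feature
    f), the k features nearest to f — by Euclidean distance over co-observed
    samples, rescaled for the number of co-observed coordinates — that are
    observed in s donate their mean value in s.  Observed values are never
    modified.  Mutation layers are re-binarized by rounding afterwards.
    """
    df = matrix.values
    n_samples, n_features = df.shape
    if k >= n_features:
        raise ValueError(f"k={k} must be smaller than the number of features ({n_features})")
    if not df.isna().any().any():
        return matrix
    if df.isna().all(axis=1).any():
        raise ValueError("a sample has no observed values; filter first")
    if df.isna().all(axis=0).any():
        raise ValueError("a feature has no observed values; filter first")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    # transpose: rows become features, so neighbours are features
    imputed = imputer.fit_transform(df.to_numpy(dtype=float).T).T
    out = pd.DataFrame(imputed, index=df.index, columns=df.columns)
    if matrix.omics_type == "mutation":
        out = out.round().clip(0, 1)
    return replace(matrix, values=out)


def align_samples(
    layers: Mapping[str, OmicsMatrix],
    clinical: pd.DataFrame | None = None,
    labels: pd.Series | None = None,
) -> MultiOmicsDataset:
    """Intersect sample IDs across layers (and clinical) and impose sorted order."""
    if not layers:
        raise ValueError("at least one omics layer is required")
    common: set | None = None
    for layer in layers.values():
        ids = set(layer.sample_ids)
        common = ids if common is None else common & ids
    if clinical is not None:
        common &= set(clinical.index)
    if not common:
        counts = {name: len(m.sample_ids) for name, m in layers.items()}
        if clinical is not None:
            counts["clinical"] = len(clinical.index)
        raise ValueError(f"empty sample intersection across inputs; per-input counts: {counts}")
    order = sorted(common)
    aligned = {
        name: replace(m, values=m.values.loc[order]) for name, m in layers.items()
    }
    clin = clinical.loc[order] if clinical is not None else None
    labs = labels.loc[order] if labels is not None else None
    return MultiOmicsDataset(layers=aligned, clinical=clin, labels=labs)


def filter_cell_lines(
    dataset: MultiOmicsDataset,
    drugs: DrugResponseTable,
    min_drug_frac: float = 0.8,
    required_layers: Sequence[str] | None = None,
    max_missing_frac: float = 0.2,
    impute_k: int = 10,
) -> tuple[MultiOmicsDataset, DrugResponseTable]:
    """Keep cell lines covering >= ``min_drug_frac`` of drugs and all required layers.

    The surviving drug table is then passed through the same >20% missingness
    filter and kNN imputation applied to omics layers.
    """
    if not 0 < min_drug_frac <= 1:
        raise ValueError("min_drug_frac must lie in (0, 1]")
    required = list(required_layers) if required_layers is not None else list(dataset.layers)
    coverage = drugs.ic50.notna().mean(axis=1)
    keep = set(coverage.index[coverage >= min_drug_frac])
    for name in required:
        keep &= set(dataset.layers[name].sample_ids)
    if not keep:
        raise ValueError("no cell line passes the drug-coverage and layer filters")
    order = [cl for cl in drugs.cell_line_ids if cl in keep]
    table = DrugResponseTable(drugs.ic50.loc[order])
    tbl = OmicsMatrix(table.ic50, "protein")  # unconstrained tag: generic numeric grid
    tbl = filter_missing(tbl, max_missing_frac)
    if tbl.values.isna().any().any():
        tbl = knn_impute(tbl, min(impute_k, tbl.values.shape[1] - 1))
    table = DrugResponseTable(tbl.values)
    layers = {
        name: replace(m, values=m.values.loc[[s for s in table.cell_line_ids if s in m.values.index]])
        for name, m in dataset.layers.items()
    }
    sub = MultiOmicsDataset(
        layers=layers,
        clinical=dataset.clinical.loc[table.cell_line_ids] if dataset.clinical is not None else None,
    )
    return sub, table


def scale_matrix(matrix: OmicsMatrix) -> OmicsMatrix:
    """Apply the per-layer scaling convention.

    mrna: per-feature z-score.  mirna: log2(x+1), then per-feature z-score.
    protein, methylation, cnv and mutation pass through unchanged (already
    scaled at source).  Zero-variance features under z-scoring become
    all-zero columns.
    """
    if matrix.values.isna().any().any():
        raise ValueError("scale_matrix requires an imputed (complete) matrix")
    if matrix.omics_type not in _ZSCORE_LAYERS:
        return replace(matrix, scaling="source")
    df = matrix.values.astype(float)
    if matrix.omics_type == "mirna":
        if (df.to_numpy() < 0).any():
            raise ValueError("mirna layer has negative values; expected raw RPM counts")
        df = np.log2(df + 1.0)
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    zero_var = sd == 0
    sd = sd.mask(zero_var, 1.0)
    df = (df - mean) / sd
    df.loc[:, zero_var] = 0.0
    tag = "zscore" if matrix.omics_type == "mrna" else "log2_zscore"
    return replace(matrix, values=df, scaling=tag)
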