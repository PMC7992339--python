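"""Per-drug IC50 binarization into sensitive/resistant calls.

Two threshold methods are provided, both operating on per-drug IC50
z-scores (lower = more sensitive):

* **K-means** — two-cluster K-means on the within-cluster sum of squares J;
  the lower-mean cluster is the sensitive class and the threshold is the
  midpoint between the largest sensitive and smallest resistant value.  For
  one-dimensional K=2 the optimal partition is a contiguous split of the
  sorted values, so the objective is minimized exactly rather than by Lloyd
  iteration.
* **Waterfall** — values sorted descending form the waterfall curve.  If
  the curve is near-linear (Pearson correlation with the rank index above
  ``pearson_cut``), the threshold is the median; otherwise the curve is
  Gaussian-smoothed and the threshold is placed at the inflection, the
  index of the largest-magnitude second difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import pearsonr


@dataclass
class ThresholdRecord:
    """Per-drug IC50 cutoff with its provenance."""

    drug_id: str
    threshold: float
    method: str  # kmeans | waterfall_inflection | waterfall_median
    linear_fit_r: float | None = None  # waterfall only
    cluster_means: tuple[float, float] | None = None  # kmeans only: (mu_low, mu_high)

    def __post_init__(self) -> None:
        if self.method == "kmeans":
            lo, hi = self.cluster_means
            if not lo < self.threshold < hi:
                raise ValueError("kmeans threshold must lie between the cluster means")


def kmeans_binarize(
    ic50, drug_id: str = "", seed: int = 0, n_restarts: int = 10
) -> tuple[ThresholdRecord, np.ndarray]:
    """Split one drug's IC50 values into sensitive (0) / resistant (1).

    Minimizes the K=2 within-cluster sum of squares exactly: in one
    dimension the optimal two-cluster partition is a contiguous split of
    the sorted values, so the global optimum of the K-means objective is
    found by scanning all n-1 splits with prefix sums (Lloyd restarts can
    stall one point short of it).  ``seed``/``n_restarts`` are accepted for
    interface stability; the solver is deterministic.

    Returns the threshold record and a {0,1} assignment vector aligned with
    the input (missing values keep assignment -1).
    """
    values = np.asarray(ic50, dtype=float)
    finite = np.isfinite(values)
    obs = values[finite]
    if np.unique(obs).size < 2:
        raise ValueError(f"drug {drug_id!r}: need >= 2 distinct finite IC50 values")
    v = np.sort(obs)
    n = v.size
    # segment SSE via prefix sums: sum(x^2) - (sum x)^2 / m
    cs, cs2 = np.cumsum(v), np.cumsum(v**2)
    m = np.arange(1, n)  # left segment sizes for cuts 1..n-1
    left = cs2[:-1] - cs[:-1] ** 2 / m
    tot_s, tot_s2 = cs[-1], cs2[-1]
    rs = tot_s - cs[:-1]
    right = (tot_s2 - cs2[:-1]) - rs**2 / (n - m)
    j = left + right
    # equal values cannot be split by any centroid assignment
    j[v[1:] == v[:-1]] = np.inf
    cut = int(np.argmin(j)) + 1
    mu_low = float(v[:cut].mean())
    mu_high = float(v[cut:].mean())
    threshold = float((v[cut - 1] + v[cut]) / 2.0)
    record = ThresholdRecord(
        drug_id=drug_id,
        threshold=threshold,
        method="kmeans",
        cluster_means=(mu_low, mu_high),
    )
    assign = np.full(values.shape, -1, dtype=int)
    assign[finite] = (values[finite] > threshold).astype(int)
    return record, assign


def waterfall_threshold(
    ic50,
    drug_id: str = "",
    pearson_cut: float = 0.95,
    smooth_sigma: float = 3.0,
    mode: str = "second",
) -> ThresholdRecord:
    """Threshold one drug by waterfall analysis of its sorted IC50 curve.

    ``mode`` selects the differential analysed on the smoothed curve:
    ``"second"`` (default) locates the largest |second difference|,
    ``"first"`` the largest |first difference|.
    """
    values = np.asarray(ic50, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 5:
        raise ValueError(f"drug {drug_id!r}: waterfall analysis needs >= 5 values")
    curve = np.sort(values)[::-1]
    ranks = np.arange(curve.size, dtype=float)
    if np.std(curve) == 0:
        r = 1.0  # flat curve is perfectly linear
    else:
        r = abs(float(pearsonr(curve, ranks).statistic))
    if r > pearson_cut:
        return ThresholdRecord(
            drug_id=drug_id,
            threshold=float(np.median(values)),
            method="waterfall_median",
            linear_fit_r=r,
        )
    smoothed = gaussian_filter1d(curve, sigma=smooth_sigma, mode="reflect")
    if mode == "second":
        diff = np.diff(smoothed, n=2)
        idx = int(np.argmax(np.abs(diff))) + 1  # centre of the stencil
    elif mode == "first":
        diff = np.diff(smoothed)
        idx = int(np.argmax(np.abs(diff)))
    else:
        raise ValueError(f"unknown differential mode {mode!r}")
    # read the cutoff off the smoothed curve: it is the analysed object, and
    # on a sharp step it interpolates the gap rather than hugging one level
    return ThresholdRecord(
        drug_id=drug_id,
        threshold=float(smoothed[idx]),
        method="waterfall_inflection",
        linear_fit_r=r,
    )


def binarize_predictions(
    predicted_ic50: pd.DataFrame, thresholds: list[ThresholdRecord]
) -> pd.DataFrame:
    """Call each predicted IC50 sensitive ('S') or resistant ('R').

    A prediction is sensitive iff it is strictly below the drug's threshold;
    missing predictions propagate as missing (NaN).
    """
    by_drug = {t.drug_id: t.threshold for t in thresholds}
    missing = [d for d in predicted_ic50.columns if d not in by_drug]
    if missing:
        raise ValueError(f"no threshold for drug(s): {missing}")
    out = pd.DataFrame(index=predicted_ic50.index, columns=predicted_ic50.columns, dtype=object)
    for drug in predicted_ic50.columns:
        col = predicted_ic50[drug].astype(float)
        out[drug] = np.where(col < by_drug[drug], "S", "R")
        out.loc[col.isna(), drug] = np.nan
    return out


def threshold_concordance(
    records_a: list[ThresholdRecord], records_b: list[ThresholdRecord]
) -> tuple[float, pd.DataFrame]:
    """Pearson r between two threshold sets over their shared drugs.

    Returns (r, paired table) — the table carries one row per shared drug
    for scatter plotting.
    """
    a = {t.drug_id: t.threshold for t in records_a}
    b = {t.drug_id: t.threshold for t in records_b}
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared drugs, got {len(shared)}")
    pairs = pd.DataFrame(
        {"threshold_a": [a[d] for d in shared], "threshold_b": [b[d] for d in shared]},
        index=pd.Index(shared, name="drug_id"),
    )
    r = float(pearsonr(pairs["threshold_a"], pairs["threshold_b"]).statistic)
    return r, pairs


def thresholds_to_tsv(records: list[ThresholdRecord], path) -> None:
    rows = [
        {
            "drug_id": t.drug_id,
            "threshold": t.threshold,
            "method": t.method,
            "linear_fit_r": t.linear_fit_r if t.linear_fit_r is not None else "NA",
        }
        for t in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
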