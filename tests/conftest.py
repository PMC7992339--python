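import numpy as np
import pandas as pd
import pytest

from lateomics.omics_io import OmicsMatrix
from lateomics.synthdata import (
    SyntheticConfig,
    generate_drug_response,
    generate_multiomics,
    generate_survival_labels,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix(rng):
    """10 x 8 continuous layer with 5 missing cells."""
    vals = rng.standard_normal((10, 8))
    df = pd.DataFrame(
        vals,
        index=[f"S{i}" for i in range(10)],
        columns=[f"g{j}" for j in range(8)],
    )
    holes = [(0, 1), (3, 4), (5, 0), (7, 7), (9, 2)]
    for r, c in holes:
        df.iat[r, c] = np.nan
    return OmicsMatrix(df, "mrna")


@pytest.fixture
def small_study():
    """Tiny planted-signal study: dataset, truth, labels and drug table."""
    cfg = SyntheticConfig(
        n_samples=80,
        omics_spec=[("mrna", 25), ("methylation", 25)],
        n_informative_per_omics=3,
        n_drugs=6,
        effect_size=1.5,
        seed=7,
    )
    dataset, truth = generate_multiomics(cfg)
    labels = generate_survival_labels(dataset, truth, cfg)
    drugs = generate_drug_response(dataset, truth, cfg)
    return cfg, dataset, truth, labels, drugs
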