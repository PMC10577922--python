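import numpy as np
import pandas as pd
import pytest

from acewas.config import CohortConfig, MethylomeConfig
from acewas.synthetic import simulate_cohort, simulate_methylome


@pytest.fixture(scope="session")
def cohort():
    """Default-condition cohort (n = 196), shared across tests."""
    return simulate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def null_methylome(cohort):
    """Methylome with no planted exposure effects."""
    cfg = MethylomeConfig(n_cpgs=1500, seed=12)
    return simulate_methylome(cohort, cfg)


@pytest.fixture(scope="session")
def toy_annotation():
    def make(positions, chrom="chr1"):
        n = len(positions)
        return pd.DataFrame(
            {
                "chrom": [chrom] * n,
                "pos": np.asarray(positions, dtype=np.int64),
                "gene": [""] * n,
                "feature": [""] * n,
            },
            index=[f"cg{i:07d}" for i in range(n)],
        )

    return make
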