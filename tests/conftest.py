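import numpy as np
import pandas as pd
import pytest

from relapse_delta import normalization
from relapse_delta.synthetic_cohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort at reduced gene count, strong DE effect."""
    cfg = SimulationConfig(seed=11, n_genes=1200, de_log2fc=2.0)
    counts, gene_info, ann, truth = simulate_cohort(cfg)
    return cfg, counts, gene_info, ann, truth


@pytest.fixture(scope="session")
def small_cohort_log(small_cohort):
    cfg, counts, gene_info, ann, truth = small_cohort
    return normalization.log2_rpkm(counts, gene_info)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with every programmed signal off (calibration reference)."""
    from relapse_delta.synthetic_cohort import null_config

    cfg = null_config(seed=23, n_genes=1000)
    counts, gene_info, ann, truth = simulate_cohort(cfg)
    return cfg, counts, gene_info, ann, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_expression():
    """Tiny deterministic 4 genes x 4 samples log-scale matrix."""
    from relapse_delta.matrix_io import ExpressionMatrix

    values = pd.DataFrame(
        {
            "s1": [1.0, 5.0, 2.0, 0.0],
            "s2": [1.0, 4.0, 2.0, 0.0],
            "s3": [3.0, 5.0, 2.0, 1.0],
            "s4": [3.0, 6.0, 2.0, 1.0],
        },
        index=pd.Index(["gA", "gB", "gC", "gD"], name="gene_id"),
    )
    return ExpressionMatrix(values, scale="log2rpkm")
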