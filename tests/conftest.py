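import numpy as np
import pandas as pd
import pytest

import ticscore as ts
from ticscore.pipeline import PipelineConfig, analyze_cohort


@pytest.fixture(scope="session")
def signature():
    return ts.make_signature(seed=1)


@pytest.fixture(scope="session")
def small_signature():
    """Tiny 4-type signature for tests where 22 types would just cost time."""
    return ts.make_signature(n_genes=44, n_cell_types=4, seed=2)


@pytest.fixture(scope="session")
def default_cohort(signature):
    """One cohort drawn at the default study conditions."""
    return ts.simulate_cohort(ts.CohortConfig(seed=7), signature)


@pytest.fixture(scope="session")
def clean_cohort(signature):
    """Noise-free, batch-free cohort (exact mixture limit)."""
    cfg = ts.CohortConfig(seed=11, noise_sd=0.0, batch_shift_sd=0.0, batch_scale_sd=0.0)
    return ts.simulate_cohort(cfg, signature)


@pytest.fixture(scope="session")
def fast_config():
    """Reduced problem sizes for the full-chain fixtures."""
    return PipelineConfig(resamples=100, boruta_max_iter=40)


@pytest.fixture(scope="session")
def default_analysis(default_cohort, signature, fast_config):
    """Full analysis of the default cohort, shared across tests."""
    return analyze_cohort(
        default_cohort.expression, signature,
        survival=default_cohort.survival, config=fast_config, seed=7,
    )


def small_expr_matrix(values, scale="FPKM", batch=None, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    b = pd.Series(batch, index=samples) if batch is not None else None
    return ts.ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), scale=scale, batch=b
    )
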