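import numpy as np
import pandas as pd
import pytest

from coexpnet import SynthConfig, generate_expression


@pytest.fixture(scope="session")
def default_config():
    return SynthConfig()


@pytest.fixture(scope="session")
def synthetic_cohort(default_config):
    """Default synthetic cohort: (expr, stages, truth)."""
    return generate_expression(default_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_block_expr():
    """Two clean 50-gene co-expression blocks over 80 samples."""
    r = np.random.default_rng(7)
    e1, e2 = r.normal(0, 1, 80), r.normal(0, 1, 80)
    X = np.vstack([
        r.uniform(0.5, 1, 50)[:, None] * e1[None, :] + r.normal(0, 0.2, (50, 80)),
        r.uniform(0.5, 1, 50)[:, None] * e2[None, :] + r.normal(0, 0.2, (50, 80)),
    ])
    genes = [f"A{i:02d}" for i in range(50)] + [f"B{i:02d}" for i in range(50)]
    expr = pd.DataFrame(X, index=genes, columns=[f"S{j:02d}" for j in range(80)])
    truth = np.array([0] * 50 + [1] * 50)
    return expr, truth
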