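import numpy as np
import pandas as pd
import pytest

from gbpscore import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """300-sample default-condition cohort shared across read-only tests."""
    cfg = SimulationConfig(n_samples=300, seed=2)
    expr, clin, mut, truth = generate_cohort(cfg)
    return cfg, expr, clin, mut, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_expr(rng):
    """Unstructured 50-gene × 10-sample matrix."""
    genes = [f"G{i:03d}" for i in range(50)]
    samples = [f"S{i}" for i in range(10)]
    return pd.DataFrame(rng.standard_normal((50, 10)), index=genes, columns=samples)
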