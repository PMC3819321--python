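import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix() -> pd.DataFrame:
    """3 genes x 2 samples with values 1..6."""
    return pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["g1", "g2", "g3"],
        columns=["A", "B"],
    )


@pytest.fixture
def random_matrix() -> pd.DataFrame:
    """Dense positive 50 x 6 matrix, fixed seed."""
    rng = np.random.default_rng(1234)
    values = np.exp2(rng.normal(4.0, 2.0, size=(50, 6)))
    return pd.DataFrame(
        values,
        index=[f"g{i:03d}" for i in range(50)],
        columns=[f"S{j}" for j in range(6)],
    )


@pytest.fixture(scope="session")
def planted():
    """Small planted-factor matrix shared across recovery tests:
    8 samples, 300 core genes, mild noise, plus truth."""
    from txnorm import SynthConfig, generate

    cfg = SynthConfig(
        n_samples=8,
        n_core_genes=300,
        n_specific_genes=24,
        n_noise_genes=60,
        noise_sigma=0.05,
        seed=77,
    )
    return generate(cfg)
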