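import numpy as np
import pandas as pd
import pytest

from crossmem import ExpressionMatrix, SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    # a larger-than-default cohort keeps planted-structure assertions away
    # from significance boundaries in fixed-seed unit tests
    return SimulationConfig(
        seed=7,
        n_patients=48,
        n_controls=24,
        n_probes=400,
        n_mouse_genes=360,
        n_shared_signal=30,
        coexpr_block_size=15,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_expr(values: np.ndarray, symbols=None, samples=None, groups=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a plain array for unit tests."""
    n_feat, n_samp = values.shape
    features = [f"f{i}" for i in range(n_feat)]
    samples = samples or [f"s{j}" for j in range(n_samp)]
    symbols = symbols if symbols is not None else [f"G{i}" for i in range(n_feat)]
    g = None
    if groups is not None:
        g = pd.Series(groups, index=samples)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=features, columns=samples),
        symbols=pd.Series(symbols, index=features),
        groups=g,
    )
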