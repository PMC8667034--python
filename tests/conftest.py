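import numpy as np
import pandas as pd
import pytest

from beanheat.simulate import GeneratorSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spec():
    return GeneratorSpec(seed=7)


@pytest.fixture
def gas_exchange_df():
    """Small hand-built gas-exchange table satisfying every invariant."""
    return pd.DataFrame({
        "genotype_id": ["G1", "G1", "G2"],
        "replicate": [1, 2, 1],
        "A": [24.0, 22.0, 18.0],
        "gs": [400.0, 380.0, 150.0],
        "E": [8.0, 7.5, 4.0],
        "Ci": [300.0, 290.0, 200.0],
        "Ca": [400.0, 400.0, 400.0],
        "Tair": [30.0, 31.0, 30.0],
        "Tleaf": [28.5, 30.0, 31.0],
        "PAR": [1300.0, 1300.0, 1300.0],
        "RH": [85.0, 80.0, 90.0],
    })
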