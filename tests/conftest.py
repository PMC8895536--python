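import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from miescreen import ExpressionMatrix, SimConfig, simulate_dataset

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def dataset():
    """Default desk-scale synthetic benchmark (planted effect/noise = 2)."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture()
def tiny_matrix():
    """4 landmark + 2 inferred features across 6 profiles, reproducible."""
    rng = np.random.default_rng(3)
    data = pd.DataFrame(
        rng.normal(size=(6, 6)),
        index=["L1", "L2", "L3", "L4", "I1", "I2"],
        columns=[f"p{i}" for i in range(6)],
    )
    fclass = pd.Series(
        ["landmark"] * 4 + ["inferred"] * 2, index=data.index
    )
    return ExpressionMatrix(data, fclass)
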