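import numpy as np
import pytest

import leafndiff as L


@pytest.fixture(scope="session")
def default_samples():
    return L.generate_samples(L.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_yields():
    return L.generate_yields(L.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def split_diffs(default_samples, default_yields):
    """Full pipeline difference set with a 0.73 train split."""
    std = L.select_standard(default_yields)
    ref = L.build_reference(default_samples, std)
    diffs = L.compute_differences(default_samples, ref)
    return L.split_train_validation(diffs, 0.73, seed=2)


@pytest.fixture(scope="session")
def table2_yields():
    """The published per-treatment yield table (kg per 667 m^2)."""
    import pandas as pd
    return pd.DataFrame({"treatment": [0, 50, 100, 150],
                         "yield": [261.99, 342.66, 387.15, 333.60]})
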