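import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gutmediate.containers import FeatureTable

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def groups12() -> pd.Series:
    ids = [f"C{i + 1:02d}" for i in range(6)] + [f"H{i + 1:02d}" for i in range(6)]
    return pd.Series(["control"] * 6 + ["hypoxia"] * 6, index=ids, name="group")


@pytest.fixture
def count_table(groups12) -> FeatureTable:
    rng = np.random.default_rng(42)
    vals = rng.integers(1, 80, size=(20, 12))
    ids = [f"Genus_{i + 1:03d}" for i in range(20)]
    return FeatureTable(
        pd.DataFrame(vals, index=ids, columns=groups12.index), groups12, "counts"
    )


@pytest.fixture
def intensity_table(groups12) -> FeatureTable:
    rng = np.random.default_rng(7)
    vals = 10.0 ** rng.normal(5.0, 0.4, size=(30, 12))
    ids = [f"Met_{i + 1:03d}" for i in range(30)]
    return FeatureTable(
        pd.DataFrame(vals, index=ids, columns=groups12.index), groups12, "intensity"
    )
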