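import sys
from pathlib import Path

import numpy as np
import pytest

# make the sibling oracles module importable regardless of invocation dir
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_table():
    """Tiny 8-sample, 4-feature table with both classes, for I/O and splits."""
    from dl_lasso.core_io import FeatureTable

    gen = np.random.default_rng(7)
    return FeatureTable(
        values=gen.standard_normal((8, 4)),
        feature_names=("fa", "fb", "fc", "fd"),
        sample_ids=tuple(f"s{i}" for i in range(8)),
        labels=np.array([0, 0, 0, 0, 1, 1, 1, 1]),
    )
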