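import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from stressmyelin.array_de import ExpressionMatrix


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """4 fragments × 4 samples, hand-enterable log2 values."""
    values = pd.DataFrame(
        {
            "HC_1": [10.0, 3.0, 8.0, 5.0],
            "HC_2": [10.2, 3.2, 8.1, 5.1],
            "CSD_1": [9.0, 3.1, 8.0, 5.2],
            "CSD_2": [9.1, 2.9, 8.2, 5.0],
        },
        index=["f1", "f2", "f3", "f4"],
    )
    groups = pd.Series(
        {"HC_1": "HC", "HC_2": "HC", "CSD_1": "CSD", "CSD_2": "CSD"}
    )
    return ExpressionMatrix(values=values, groups=groups)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170418)
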