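import numpy as np
import pandas as pd
import pytest

from pyrosynergy.io_formats import (
    DrugActivityPanel,
    ExpressionMatrix,
    GeneSet,
    SurvivalTable,
)


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    """3 genes x 4 samples, two classes."""
    data = pd.DataFrame(
        [[1.0, 2.0, 5.0, 6.0], [3.0, 3.5, 1.0, 0.5], [2.0, 2.0, 2.0, 2.0]],
        index=["AIM2", "BCL2", "GBP5"],
        columns=["s1", "s2", "s3", "s4"],
    )
    classes = {"s1": "normal", "s2": "normal", "s3": "tumor", "s4": "tumor"}
    return ExpressionMatrix(data, classes)


@pytest.fixture
def toy_survival() -> SurvivalTable:
    return SurvivalTable(
        pd.DataFrame(
            {"time": [2.0, 5.0, 8.0, 12.0, 20.0, 30.0],
             "event": [1, 1, 1, 0, 1, 0]},
            index=pd.Index([f"p{i}" for i in range(6)], name="sample"),
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
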