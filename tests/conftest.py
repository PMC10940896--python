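import numpy as np
import pandas as pd
import pytest

from foldwise.data_model import TypedDataset, assign_types
from foldwise.synthetic import make_confounded_data, make_regression_data


@pytest.fixture
def small_regression():
    """120 samples, 8 features, 4 informative, mild noise."""
    ds, truth = make_regression_data(
        n=120, p=8, k_informative=4, beta_scale=1.0, noise_sd=0.5, seed=11
    )
    return ds, truth


@pytest.fixture
def confounded():
    """Age-confounded case/control data with no direct signal."""
    ds, truth = make_confounded_data(n=240, p=12, seed=21)
    return ds, truth


@pytest.fixture
def typed_toy():
    """Tiny hand-built table with mixed column types."""
    table = pd.DataFrame(
        {
            "height": [1.7, 1.8, 1.6, 1.75, 1.9, 1.65],
            "weight": [70.0, 82.0, 55.0, 74.0, 95.0, 60.0],
            "site": ["a", "b", "a", "b", "a", "b"],
            "age": [34.0, 51.0, 28.0, 40.0, 66.0, 31.0],
            "diagnosis": ["control", "case", "control", "case", "case", "control"],
        }
    )
    ds = TypedDataset(table=table, target="diagnosis")
    return assign_types(
        ds,
        type_map={"confound": ["age"], "categorical": ["site"]},
        target="diagnosis",
    )
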