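import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ivdirect.simulate import generate_dataset, preset
from ivdirect.survey import StudyTable

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def forward_table():
    table, truth = generate_dataset(preset("forward_strong", seed=42))
    return table, truth


@pytest.fixture
def small_table():
    """Tiny hand-built study table with some missing cells."""
    df = pd.DataFrame(
        {
            "Z": [1, 0, 1, 0, 1, 1, 0, 0],
            "T": [0, 2, 4, 1, np.nan, 3, 0, 2],
            "Y": [5, 3, 4, np.nan, 2, 5, 1, 3],
            "x_a": [0, 1, 0, 1, 0, np.nan, 1, 0],
            "x_b": [0, 0, 1, 2, 1, 2, 0, 1],
            "cancer": [1, 1, 1, 1, 1, 1, 1, 1],
        },
        dtype=float,
    )
    return StudyTable(df=df, outcomes=["Y"], confounders=["x_a", "x_b"])
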