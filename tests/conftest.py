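import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from proteoflow.io import IntensityMatrix

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix():
    """3 proteins x 4 samples, log2 scale, one missing cell."""
    values = pd.DataFrame(
        {
            "s1": [10.0, 12.0, 20.0],
            "s2": [10.5, 12.5, np.nan],
            "s3": [11.0, 13.0, 21.0],
            "s4": [11.5, 13.5, 21.5],
        },
        index=pd.Index(["P1", "P2", "P3"], name="protein_id"),
    )
    return IntensityMatrix(values, scale="log2")


@pytest.fixture
def complete_matrix(rng):
    """20 proteins x 6 samples, complete, log2 scale."""
    values = pd.DataFrame(
        rng.normal(20, 2, size=(20, 6)),
        index=[f"P{i:02d}" for i in range(20)],
        columns=[f"s{j}" for j in range(6)],
    )
    return IntensityMatrix(values, scale="log2")
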