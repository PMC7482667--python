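import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_log2_matrix(rng):
    """8 proteins x 10 samples on the log2 scale, two groups of 5."""
    from lfqnet.io import AbundanceMatrix

    names = [f"P{i:04d}" for i in range(8)]
    samples = [f"MGI_{i:02d}" for i in range(5)] + [f"MGII_{i:02d}" for i in range(5)]
    values = rng.normal(28.0, 0.5, size=(8, 10))
    matrix = AbundanceMatrix(
        pd.DataFrame(values, index=names, columns=samples), scale="log2"
    )
    metadata = pd.Series(["MGI"] * 5 + ["MGII"] * 5, index=samples, name="group")
    return matrix, metadata
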