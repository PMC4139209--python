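import numpy as np
import pytest

from atromir.matrix import ExpressionMatrix, SampleMeta


@pytest.fixture
def small_matrix():
    """3 features x 4 samples (2 conditions x 2 replicates), one masked cell."""
    values = np.array([
        [0.0, 0.1, 1.0, 1.1],
        [0.2, -0.1, -1.0, np.nan],
        [0.0, 0.0, 0.0, 0.0],
    ])
    meta = {
        "c1": SampleMeta("control"), "c2": SampleMeta("control"),
        "t1": SampleMeta("Den7", 7.0), "t2": SampleMeta("Den7", 7.0),
    }
    return ExpressionMatrix(
        feature_ids=["f1", "f2", "f3"],
        sample_ids=["c1", "c2", "t1", "t2"],
        values=values,
        sample_meta=meta,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20140602)
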