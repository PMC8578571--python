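import numpy as np
import pandas as pd
import pytest

from samnet.expression_io import ExpressionMatrix, GroupDesign


def make_matrix(values, feature_ids=None, sample_ids=None, scale="log2"):
    values = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=feature_ids, columns=sample_ids),
                            scale=scale)


def make_design(n_control, n_experimental, sample_ids=None):
    sample_ids = sample_ids or [f"s{i}" for i in range(n_control + n_experimental)]
    return GroupDesign({s: ("control" if i < n_control else "experimental")
                        for i, s in enumerate(sample_ids)})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_two_group(rng):
    """Random 30-gene, 3 vs 3 log2 matrix with no planted effects."""
    X = rng.normal(8.0, 0.4, size=(30, 6))
    return make_matrix(X), make_design(3, 3)
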