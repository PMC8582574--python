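import numpy as np
import pytest

from mirnet import ExpressionMatrix, ValueKind


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    return ExpressionMatrix(
        feature_ids=["f1", "f2", "f3"],
        sample_ids=["s1", "s2"],
        values=np.array([[1.0, 2.0], [3.0, 4.5], [0.0, 7.25]]),
        value_kind=ValueKind.RPM,
    )


def make_matrix(values, kind=ValueKind.RPM, prefix="f", samples=None):
    values = np.asarray(values, dtype=float)
    n_f, n_s = values.shape
    return ExpressionMatrix(
        feature_ids=[f"{prefix}{i + 1}" for i in range(n_f)],
        sample_ids=samples or [f"s{j + 1}" for j in range(n_s)],
        values=values,
        value_kind=kind,
    )
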