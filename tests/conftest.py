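import numpy as np
import pytest

from hsm.data import CohortDesign, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, prefix="s", fprefix="g", stages=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ExpressionMatrix(
        values,
        [f"{prefix}{i}" for i in range(n)],
        [f"{fprefix}{j}" for j in range(p)],
        stages,
    )


@pytest.fixture
def toy_matrix():
    """3 samples x 2 features with hand-checkable values."""
    return make_matrix([[1.0, 4.0], [2.0, 5.0], [3.0, 7.0]])


@pytest.fixture
def separated_cohort(rng):
    """Two 8-sample groups separated along feature 0 only (p=5 total);
    the other features are pure noise.  Returns (X, design)."""
    p = 5
    VH = rng.standard_normal((8, p))
    VD = rng.standard_normal((8, p))
    VD[:, 0] += 6.0
    values = np.vstack([VH, VD])
    ids = [f"h{i}" for i in range(8)] + [f"d{i}" for i in range(8)]
    X = ExpressionMatrix(values, ids, [f"g{j}" for j in range(p)])
    design = CohortDesign(ids[:8], ids[8:])
    return X, design
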