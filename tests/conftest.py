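import numpy as np
import pytest

from diffconet import ExpressionMatrix, PathwayCollection


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expression(rng):
    """Two 30-sample, 8-gene groups drawn from one multivariate normal."""
    genes = [f"g{i}" for i in range(1, 9)]
    cov = np.eye(8) + 0.3
    X1 = rng.multivariate_normal(np.zeros(8), cov, size=30)
    X2 = rng.multivariate_normal(np.zeros(8), cov, size=30)
    return (
        ExpressionMatrix(X1, genes, group_label="a"),
        ExpressionMatrix(X2, genes, group_label="b"),
    )


@pytest.fixture
def toy_pathways():
    return PathwayCollection(
        [
            ("P1", frozenset({"g1", "g2", "g3", "g4"})),
            ("P2", frozenset({"g5", "g6", "g7", "g8"})),
        ],
        source="toy",
    )


def random_pd_precision(rng, m):
    """A random symmetric positive definite precision matrix."""
    A = rng.normal(size=(m, m))
    omega = A @ A.T + m * np.eye(m)
    return (omega + omega.T) / 2.0
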