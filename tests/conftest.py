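import numpy as np
import pytest

from topopca import ExpressionMatrix, SyntheticSpec, simulate_counts, zscore


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_counts():
    """5 genes x 4 cells, non-negative, with one constant-zero gene."""
    values = np.array(
        [
            [0.0, 0.0, 0.0, 0.0],  # zero variance
            [1.0, 2.0, 3.0, 4.0],
            [10.0, 0.0, 10.0, 0.0],
            [5.0, 5.0, 5.0, 6.0],
            [0.0, 1.0, 0.0, 2.0],
        ]
    )
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(5)],
        [f"c{j}" for j in range(4)],
        ["a", "a", "b", "b"],
    )


@pytest.fixture(scope="session")
def blobs_xm():
    """Well-separated 3-class synthetic matrix, preprocessed and z-scored."""
    from topopca import preprocess

    xm = simulate_counts(
        SyntheticSpec(
            n_classes=3,
            cells_per_class=40,
            n_genes=300,
            cluster_separation=6.0,
            dropout_rate=0.2,
            seed=7,
        )
    )
    return zscore(preprocess(xm))


def blob_matrix(seed: int, M: int = 100, N: int = 100, n_classes: int = 3,
                spread: float = 4.0):
    """Centered continuous blob data (genes x cells) plus labels."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, spread, size=(M, n_classes))
    lab = np.repeat(np.arange(n_classes), N // n_classes + 1)[:N]
    X = centers[:, lab] + rng.normal(0, 1, size=(M, N))
    X = X - X.mean(axis=1, keepdims=True)
    return X, lab
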