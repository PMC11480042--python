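import numpy as np
import pytest
from sklearn.datasets import make_blobs

from reportuq import EmbeddingTable, generate_corpus


@pytest.fixture(scope="session")
def blob_data():
    """Separable 3-class blobs (n=600, d=5): Bayes accuracy ~ 1."""
    X, y = make_blobs(n_samples=600, centers=3, n_features=5,
                      cluster_std=1.0, random_state=0)
    return {"X_train": X[:450], "y_train": y[:450],
            "X_test": X[450:], "y_test": y[450:],
            "X_val": X[400:450], "y_val": y[400:450]}


@pytest.fixture(scope="session")
def corpus5k():
    """Default-condition corpus at n=5000 (seed 1), reused across checks."""
    return generate_corpus(n=5000, seed=1)


@pytest.fixture()
def toy_table():
    return EmbeddingTable({
        "a": np.array([1.0, 0.0]),
        "b": np.array([0.0, 1.0]),
        "c": np.array([2.0, -1.0]),
    })
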