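import numpy as np
import pytest

from roplsda import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_raw_table():
    values = np.array([[1.0, 10.0], [100.0, 1000.0]])
    return FeatureTable(["s1", "s2"], ["f1", "f2"], values, "raw")


@pytest.fixture
def two_blob_data(rng):
    """n=40, d=10: two classes separated by 10 sd on the first 3 features."""
    X = rng.normal(size=(40, 10))
    X[:20, :3] += 10.0
    y = np.array(["a"] * 20 + ["b"] * 20)
    return X, y


def pls1_oracle(X, y_coded):
    """Brute-force single-component NIPALS PLS1 on centered data.

    Independent reference for the predictive component: iterate
    w <- X'u / ||X'u||, t <- Xw, q <- u't/t't, u <- y q ... which for a
    single y column converges immediately to w = X'y/||X'y||. The loop is
    kept literal so the oracle stays independent of the package code.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    u = np.asarray(y_coded, dtype=float)
    u = u - u.mean()
    w_old = np.zeros(X.shape[1])
    for _ in range(500):
        w = Xc.T @ u
        w = w / np.linalg.norm(w)
        t = Xc @ w
        # with a single response column u never updates, so the loop
        # converges on the first pass; kept literal as the reference
        if np.linalg.norm(w - w_old) < 1e-14:
            break
        w_old = w
    return w, t
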