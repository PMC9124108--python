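import numpy as np
import pytest

from gwanfis import ExpressionDataset, SyntheticSpec, generate_synthetic, zscore_normalize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """4 samples x 3 genes with a hand-checkable first gene column."""
    return ExpressionDataset(
        values=np.array([
            [1.0, 5.0, 0.2],
            [2.0, 5.0, 0.4],
            [3.0, 5.0, 0.8],
            [2.0, 5.0, 0.1],
        ]),
        labels=np.array([0, 0, 1, 1]),
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture(scope="session")
def synthetic_ds():
    """The standard recovery fixture: 60 samples x 200 genes, 10 informative."""
    return generate_synthetic(SyntheticSpec(
        n_samples=60, n_genes=200, n_informative=10, shift=2.0,
        class1_fraction=0.4, seed=11,
    ))


@pytest.fixture(scope="session")
def normalized_synthetic(synthetic_ds):
    return zscore_normalize(synthetic_ds)


@pytest.fixture(scope="session")
def separable_dataset():
    """Small dataset where gene 0 perfectly separates the classes."""
    rng = np.random.default_rng(42)
    n, d = 30, 20
    labels = np.array([0, 1] * (n // 2))
    values = rng.standard_normal((n, d))
    values[:, 0] = labels * 6.0 + rng.standard_normal(n) * 0.1
    ds = ExpressionDataset(
        values=values,
        labels=labels,
        gene_ids=[f"g{j}" for j in range(d)],
        sample_ids=[f"s{i}" for i in range(n)],
    )
    return zscore_normalize(ds)


@pytest.fixture(scope="session")
def blob_xy():
    """Two well-separated Gaussian blobs in 2-D with 0/1 labels (n=80)."""
    rng = np.random.default_rng(7)
    n = 40
    x0 = rng.standard_normal((n, 2)) * 0.5 + np.array([-2.0, -2.0])
    x1 = rng.standard_normal((n, 2)) * 0.5 + np.array([2.0, 2.0])
    X = np.vstack([x0, x1])
    y = np.array([0] * n + [1] * n)
    perm = rng.permutation(2 * n)
    return X[perm], y[perm]
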