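import numpy as np
import pytest

from radtx.io import ExpressionMatrix, FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr():
    """3 genes x 4 samples, two per class."""
    values = np.array(
        [
            [8.0, 9.0, 7.0, 7.0],
            [5.0, 5.5, 5.2, 5.1],
            [10.0, 10.5, 8.0, 8.5],
        ]
    )
    return ExpressionMatrix(
        ["100", "200", "300"],
        ["s1", "s2", "s3", "s4"],
        values,
        ["cancer", "cancer", "normal", "normal"],
        batch_id="toy",
    )


@pytest.fixture
def small_features():
    values = np.array(
        [
            [1.0, 2.0, 3.0],
            [2.0, 1.0, 3.0],
            [3.0, 4.0, 3.0],
            [4.0, 3.0, 3.0],
        ]
    )
    return FeatureTable(
        ["s1", "s2", "s3", "s4"],
        ["original_glcm_f0001", "original_shape_f0002", "wavelet_LLH_glszm_f0003"],
        values,
    )


def make_expr(values, gene_prefix="g", sample_prefix="s", classes=None, batch="b"):
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    return ExpressionMatrix(
        [f"{gene_prefix}{i}" for i in range(g)],
        [f"{sample_prefix}{j}" for j in range(n)],
        values,
        classes or [],
        batch,
    )
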