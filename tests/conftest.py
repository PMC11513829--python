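import numpy as np
import pytest

from pdomics.io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def small_matrix(rng):
    """A 20-gene x 10-sample matrix with two labelled groups."""
    genes = [f"g{i}" for i in range(20)]
    samples = [f"s{i}" for i in range(10)]
    values = rng.normal(5, 2, size=(20, 10))
    metadata = {
        s: {"group": "healthy" if i < 5 else "CD"} for i, s in enumerate(samples)
    }
    return ExpressionMatrix(gene_ids=genes, sample_ids=samples,
                            values=values, metadata=metadata)


def brute_force_step(series):
    """Exhaustive one-step fit: (k, sse, mu_left, mu_right) at the best split.

    Independent of the production path: plain Python loops over every split
    point, residuals summed directly, smallest k wins ties.
    """
    x = [float(v) for v in series]
    n = len(x)
    best = None
    for k in range(1, n):
        mu_l = sum(x[:k]) / k
        mu_r = sum(x[k:]) / (n - k)
        sse = sum((v - mu_l) ** 2 for v in x[:k]) + sum((v - mu_r) ** 2 for v in x[k:])
        if best is None or sse < best[1] - 1e-12:
            best = (k, sse, mu_l, mu_r)
    return best
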