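import numpy as np
import pytest

from probic.matrix import ExpressionMatrix
from probic.synthetic import implanted_demo_config, simulate


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """Deterministic 6 genes x 4 arrays with one missing value."""
    rng = np.random.default_rng(42)
    values = rng.normal(0.0, 1.0, size=(6, 4))
    values[4, 2] = np.nan
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(6)],
        array_ids=[f"a{j}" for j in range(4)],
        values=values,
    )


@pytest.fixture(scope="session")
def demo():
    """One standard implanted-bicluster compendium plus its ground truth."""
    matrix, truth = simulate(implanted_demo_config(rng_seed=0))
    return matrix, truth


def jaccard(a, b) -> float:
    sa, sb = set(a), set(b)
    return len(sa & sb) / len(sa | sb) if (sa | sb) else 1.0
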