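import numpy as np
import pytest

from tdfe import ExpressionMatrix, ExpressionTensor


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_matrix(rng):
    """Small random expression matrix (8 features x 5 samples)."""
    return ExpressionMatrix(
        rng.standard_normal((8, 5)),
        tuple(f"g{i}" for i in range(8)),
        tuple(f"s{j}" for j in range(5)),
    )


@pytest.fixture
def random_tensor(rng):
    """Random 6 x 3 x 2 x 2 gene-mode tensor."""
    return ExpressionTensor(
        rng.standard_normal((6, 3, 2, 2)),
        mode_names=("gene", "cell_line", "treatment", "replicate"),
        gene_mode="gene",
    )
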