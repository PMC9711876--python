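import numpy as np
import pandas as pd
import pytest

from arascore.expression import ExpressionMatrix, GenePanel


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """12-gene, 3-sample matrix with ties, small enough to enumerate."""
    rng = np.random.default_rng(42)
    values = rng.integers(0, 20, size=(12, 3)).astype(float)  # ints force ties
    genes = [f"G{i}" for i in range(10)] + ["PANEL_A", "PANEL_B"]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=["s1", "s2", "s3"]))


@pytest.fixture
def toy_panel() -> GenePanel:
    return GenePanel(("PANEL_A", "PANEL_B"))


def random_matrix(rng, n_genes=None, n_samples=None) -> ExpressionMatrix:
    """Random small matrix with planted ties (integer-valued abundances)."""
    n_genes = n_genes or int(rng.integers(5, 51))
    n_samples = n_samples or int(rng.integers(1, 11))
    values = rng.integers(0, 12, size=(n_genes, n_samples)).astype(float)
    genes = [f"G{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
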