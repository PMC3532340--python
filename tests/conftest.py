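import numpy as np
import pytest

from coexrif import ExpressionDataset


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """Five genes, 3+3 samples, reproducible values."""
    rng = np.random.default_rng(7)
    gene_ids = [f"g{i}" for i in range(1, 6)]
    sample_ids = [f"s{i}" for i in range(1, 7)]
    values = rng.normal(8.0, 2.0, size=(5, 6))
    condition_of = {s: (1 if i < 3 else 2) for i, s in enumerate(sample_ids)}
    return ExpressionDataset(
        gene_ids=gene_ids, sample_ids=sample_ids, values=values, condition_of=condition_of
    )


def make_dataset(values: np.ndarray, n1: int, n2: int) -> ExpressionDataset:
    """Wrap a raw matrix into a dataset with the first n1 columns as condition 1."""
    values = np.asarray(values, dtype=float)
    n_genes = values.shape[0]
    gene_ids = [f"g{i}" for i in range(1, n_genes + 1)]
    sample_ids = [f"s{i}" for i in range(1, n1 + n2 + 1)]
    condition_of = {s: (1 if i < n1 else 2) for i, s in enumerate(sample_ids)}
    return ExpressionDataset(
        gene_ids=gene_ids, sample_ids=sample_ids, values=values, condition_of=condition_of
    )
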