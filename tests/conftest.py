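import numpy as np
import pytest

from rsgsa import ExpressionDataset, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """8 samples x 6 genes, two classes, one obviously informative gene."""
    rng = np.random.default_rng(7)
    values = rng.normal(size=(8, 6))
    labels = np.array(["a", "a", "a", "a", "b", "b", "b", "b"], dtype=object)
    values[:, 2] += np.where(labels == "b", 3.0, 0.0)
    return ExpressionDataset(
        values=values,
        labels=labels,
        gene_ids=[f"g{i}" for i in range(6)],
        sample_ids=[f"s{i}" for i in range(8)],
    )


@pytest.fixture
def planted_dataset():
    """Synthetic 40 x 120 dataset with 4 planted blocks (1 + 2 companions)."""
    spec = SyntheticSpec(
        n_samples=40, n_genes=120, n_informative=4, block_size=2,
        effect_size=2.0, within_block_corr=0.95, seed=11,
    )
    dataset, truth = generate(spec)
    return dataset, truth
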