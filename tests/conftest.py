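import numpy as np
import pandas as pd
import pytest

from sexcpm import datasets
from sexcpm.types import ChromosomeMap, CountsMatrix, CpmMatrix


@pytest.fixture(scope="session")
def reference():
    """Bundled conceptus dataset: (CpmMatrix, published sigma, labels)."""
    return datasets.load_conceptus_cpm()


@pytest.fixture(scope="session")
def reference_chrom_map():
    return datasets.conceptus_chrom_map()


@pytest.fixture()
def small_counts():
    """3 genes × 2 samples with known values."""
    frame = pd.DataFrame(
        [[3, 10], [1, 0], [6, 10]],
        index=pd.Index(["geneA", "geneB", "geneC"], name="gene_id"),
        columns=["S1", "S2"],
    )
    return CountsMatrix(frame)


def random_counts(seed: int, n_genes: int = 50, n_samples: int = 5) -> CountsMatrix:
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        rng.integers(0, 1000, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    # guarantee positive library sizes
    frame.iloc[0] += 1
    return CountsMatrix(frame)


def cpm_from_frame(values, gene_ids, sample_ids) -> CpmMatrix:
    return CpmMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids, dtype=float))
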