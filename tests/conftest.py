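import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from smcmn import (
    BinaryMutationMatrix,
    CorrelationMatrix,
    filter_low_frequency_genes,
    fixture_B,
    generate_planted_dataset,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def fixture_b() -> BinaryMutationMatrix:
    return fixture_B()


@pytest.fixture
def zero_w3(fixture_b) -> CorrelationMatrix:
    n = fixture_b.n_genes
    return CorrelationMatrix(fixture_b.gene_ids, np.zeros((n, n)))


def planted(**kwargs):
    """A planted instance with the standard low-frequency filter applied,
    as the search pipeline would see it."""
    inst = generate_planted_dataset(**kwargs)
    A = filter_low_frequency_genes(inst.A, 0.005)
    return A, inst.W, inst.planted_genes


def make_matrix(supports: dict[str, set[int]], n_samples: int) -> BinaryMutationMatrix:
    """Build a binary mutation matrix from explicit per-gene support sets."""
    genes = list(supports)
    values = np.zeros((n_samples, len(genes)), dtype=np.int8)
    for j, g in enumerate(genes):
        for i in supports[g]:
            values[i, j] = 1
    samples = [f"s{i + 1}" for i in range(n_samples)]
    return BinaryMutationMatrix(samples, genes, values)


def make_correlation(gene_ids, pairs: dict[tuple[str, str], float]) -> CorrelationMatrix:
    """Symmetric correlation matrix from a dict of unordered pair weights."""
    n = len(gene_ids)
    pos = {g: i for i, g in enumerate(gene_ids)}
    w = np.zeros((n, n))
    for (a, b), val in pairs.items():
        w[pos[a], pos[b]] = w[pos[b], pos[a]] = val
    return CorrelationMatrix(list(gene_ids), w)


def write_tsv_matrix(path, matrix: BinaryMutationMatrix) -> None:
    pd.DataFrame(
        matrix.values, index=matrix.sample_ids, columns=matrix.gene_ids
    ).to_csv(path, sep="\t", index_label="sample")
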