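"""Permutation significance test for an identified gene set.

The null distribution is formed by drawing K genes uniformly at random
(without replacement within each draw) from the full post-filter gene
universe — no connectivity or cluster constraint — and scoring each draw with
the same objective used to find the observed set.  The p-value is the fraction
of null draws whose weight STRICTLY exceeds the observed weight; ties do not
count against the observed set.  Resolution is 1/n_draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .matrices import BinaryMutationMatrix, CorrelationMatrix
from .scoring import SubsetScorer

__all__ = ["SignificanceResult", "random_test"]


@dataclass(frozen=True)
class SignificanceResult:
    p_value: float
    n_draws: int
    observed_weight: float
    null_weights: tuple[float, ...]


def random_test(
    A: BinaryMutationMatrix,
    W: CorrelationMatrix | None,
    genes: Iterable[str],
    n_draws: int = 1000,
    rng: np.random.Generator | int | None = None,
    use_network: bool = True,
) -> SignificanceResult:
    """Compare the weight of ``genes`` against random same-size gene sets."""
    genes = list(genes)
    k = len(genes)
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    if k > A.n_genes:
        raise ValueError(f"gene set size {k} exceeds the {A.n_genes} genes available")
    rng = np.random.default_rng(rng)
    scorer = SubsetScorer(A, W, use_network=use_network)
    observed = scorer.weight_of_genes(genes)
    null = np.empty(n_draws)
    for i in range(n_draws):
        idx = rng.choice(A.n_genes, size=k, replace=False)
        null[i] = scorer.weight(idx)
    p = float((null > observed).sum()) / n_draws
    return SignificanceResult(p, n_draws, observed, tuple(null.tolist()))
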