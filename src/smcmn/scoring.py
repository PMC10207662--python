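"""Model mathematics: coverage, relative Hamming distance, mutual exclusivity,
network connectivity, the combined submatrix weight, and the classical
maximum-weight-submatrix baseline.

Notation.  A is the binary mutation matrix (samples x genes); Gamma(g) is the
support of gene g (samples in which it is altered); M is the submatrix induced
by a gene set G_M of size K.  The combined weight maximized by the search is

    W(M) = CO(M) + ME(M) + N(M)

with coverage CO(M) = |Gamma(M)| / max_g |Gamma(g)| (the max runs over ALL
genes of A, so CO can exceed 1), mutual exclusivity ME(M) the average relative
Hamming distance between each member and the rest of the set, and N(M) the
mean pairwise network weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .matrices import BinaryMutationMatrix, CorrelationMatrix

__all__ = [
    "GeneSetScore",
    "coverage",
    "rhd_pair",
    "rhd_gene_to_set",
    "mutual_exclusivity",
    "network_score",
    "smcmn_weight",
    "mwsm_weight",
    "detect_inclusions",
    "SubsetScorer",
]


@dataclass(frozen=True)
class GeneSetScore:
    """The decomposed weight of one gene set."""

    coverage: float
    mutual_exclusivity: float
    network: float
    total: float
    covered_samples: frozenset[int]

    def as_dict(self) -> dict:
        return {
            "coverage": self.coverage,
            "mutual_exclusivity": self.mutual_exclusivity,
            "network": self.network,
            "total": self.total,
            "n_covered_samples": len(self.covered_samples),
        }


def _gene_indices(A: BinaryMutationMatrix, genes: Iterable[str]) -> list[int]:
    return [A.gene_index(g) for g in genes]


def coverage(A: BinaryMutationMatrix, genes: Iterable[str]) -> float:
    """|Gamma(M)| normalized by the largest single-gene support in A.

    The denominator runs over every gene of A, not just the set, so a set
    whose union exceeds the best single gene scores above 1.
    """
    idx = _gene_indices(A, genes)
    if not idx:
        raise ValueError("coverage of an empty gene set is undefined")
    covered = int(A.values[:, idx].any(axis=1).sum())
    denom = int(A.support_sizes.max())
    if denom == 0:
        raise ValueError("coverage undefined: no gene in A has a nonempty support")
    return covered / denom


def rhd_pair(A: BinaryMutationMatrix, g_j: str, g_k: str) -> float:
    """Relative Hamming distance of g_j toward g_k.

    The fraction of g_j's mutated samples in which g_k is NOT mutated:
    0 iff Gamma(g_j) is contained in Gamma(g_k); 1 iff the supports are
    disjoint.  Asymmetric in general.
    """
    if g_j == g_k:
        raise ValueError("relative Hamming distance requires two distinct genes")
    j = A.gene_index(g_j)
    k = A.gene_index(g_k)
    nj = int(A.support_sizes[j])
    if nj == 0:
        raise ValueError(f"gene {g_j!r} has an empty support; RHD is undefined")
    exclusive = int(((A.values[:, j] == 1) & (A.values[:, k] == 0)).sum())
    return exclusive / nj


def rhd_gene_to_set(A: BinaryMutationMatrix, g_j: str, genes: Iterable[str]) -> float:
    """Mean RHD from g_j toward each other member of the set (K-1 terms)."""
    genes = list(genes)
    if g_j not in genes:
        raise ValueError(f"gene {g_j!r} must be a member of the set")
    others = [g for g in genes if g != g_j]
    if not others:
        raise ValueError("RHD toward a set requires at least two member genes")
    return sum(rhd_pair(A, g_j, g_k) for g_k in others) / len(others)


def mutual_exclusivity(A: BinaryMutationMatrix, genes: Iterable[str]) -> float:
    """Average over members of the gene-to-set RHD; in [0, 1].

    1 when supports are pairwise disjoint (perfect exclusivity); 0 when all
    supports are identical.  Genes with empty support are an error — they
    cannot survive the frequency filter, so their appearance signals upstream
    misuse.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("mutual exclusivity requires at least two genes")
    return sum(rhd_gene_to_set(A, g, genes) for g in genes) / len(genes)


def network_score(W: CorrelationMatrix, genes: Iterable[str]) -> float:
    """Mean of the ordered off-diagonal weights of the extracted submatrix.

    Equals the arithmetic mean of the C(K, 2) unordered pairwise weights for a
    symmetric W; lies in [0, 1].
    """
    idx = [W.gene_index(g) for g in genes]
    m = len(idx)
    if m < 2:
        raise ValueError("network score requires at least two genes")
    sub = W.values[np.ix_(idx, idx)]
    return float(sub.sum()) / (m * (m - 1))


def smcmn_weight(
    A: BinaryMutationMatrix,
    W: CorrelationMatrix | None,
    genes: Iterable[str],
    use_network: bool = True,
) -> GeneSetScore:
    """The combined weight W(M) = CO(M) + ME(M) + N(M) of a gene set.

    With ``use_network=False`` (or W absent) the network term is dropped and
    the objective reduces to coverage + exclusivity alone.
    """
    genes = list(genes)
    co = coverage(A, genes)
    me = mutual_exclusivity(A, genes)
    if use_network and W is not None:
        net = network_score(W, genes)
    else:
        net = 0.0
    idx = _gene_indices(A, genes)
    covered = frozenset(np.flatnonzero(A.values[:, idx].any(axis=1)).tolist())
    return GeneSetScore(co, me, net, co + me + net, covered)


def mwsm_weight(A: BinaryMutationMatrix, genes: Iterable[str]) -> int:
    """The classical maximum-weight-submatrix score 2|Gamma(M)| - sum |Gamma(g)|.

    Coverage minus overlap; the baseline this model's exclusivity measure
    refines (it cannot penalize inclusion relationships).
    """
    idx = _gene_indices(A, genes)
    if not idx:
        raise ValueError("weight of an empty gene set is undefined")
    union = int(A.values[:, idx].any(axis=1).sum())
    return 2 * union - int(A.support_sizes[idx].sum())


def detect_inclusions(A: BinaryMutationMatrix, genes: Iterable[str]) -> set[tuple[str, str]]:
    """All ordered pairs (g, h) within the set with Gamma(g) ⊆ Gamma(h).

    An inclusion (RHD(g, h) = 0) means every sample mutating g also mutates h
    — the degenerate structure the exclusivity measure is designed to reject.
    """
    genes = list(genes)
    out: set[tuple[str, str]] = set()
    for g, h in combinations(genes, 2):
        if rhd_pair(A, g, h) == 0.0:
            out.add((g, h))
        if rhd_pair(A, h, g) == 0.0:
            out.add((h, g))
    return out


class SubsetScorer:
    """Vectorized scorer for many gene subsets of one (A, W) instance.

    Precomputes pairwise exclusive-sample counts so that each subset weight is
    O(K^2 + |P|) instead of rescanning the matrix; used by the genetic search
    and the permutation test, and kept exactly consistent with the
    function-level definitions above (asserted in the test suite).
    """

    def __init__(
        self,
        A: BinaryMutationMatrix,
        W: CorrelationMatrix | None = None,
        use_network: bool = True,
    ) -> None:
        self.A = A
        self.W = W
        self.use_network = use_network and W is not None
        self._bool = A.values.astype(bool)
        self.support_sizes = A.support_sizes.astype(np.int64)
        overlap = self._bool.T.astype(np.int64) @ self._bool.astype(np.int64)
        # exclusive[j, k] = |Gamma(g_j) \ Gamma(g_k)|
        self._exclusive = self.support_sizes[:, None] - overlap
        self._max_support = int(self.support_sizes.max(initial=0))
        if self.use_network:
            self._w = self.W.reindex(A.gene_ids).values
        else:
            self._w = None

    def weight(self, idx: Sequence[int]) -> float:
        """W(M) for the gene subset given by column indices of A."""
        idx = np.asarray(idx, dtype=int)
        k = len(idx)
        covered = int(self._bool[:, idx].any(axis=1).sum())
        co = covered / self._max_support
        supports = self.support_sizes[idx]
        excl = self._exclusive[np.ix_(idx, idx)]
        # mean over ordered pairs of RHD(g_j, g_k) = excl[j,k]/|Gamma(g_j)|
        rhd = excl / supports[:, None]
        me = (rhd.sum() - np.trace(rhd)) / (k * (k - 1))
        total = co + me
        if self._w is not None:
            total += float(self._w[np.ix_(idx, idx)].sum()) / (k * (k - 1))
        return float(total)

    def weight_of_genes(self, genes: Iterable[str]) -> float:
        return self.weight([self.A.gene_index(g) for g in genes])
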