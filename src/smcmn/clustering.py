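"""Gene clustering preprocessing that prunes the combinatorial search space.

For every gene g two candidate sets are built once per run:

* ``c1(g)`` — genes at relative Hamming distance >= mu from g (near-exclusive
  partners; the RHD is taken in the asymmetric direction from the cluster
  owner g toward the candidate, exactly as the model defines it);
* ``c2(g)`` — genes whose network weight with g is >= nu (well-connected
  partners).

During chromosome construction the pool of genes eligible to extend a partial
set X is the intersection of the c1 sets of X's members, intersected with the
union of their c2 sets, minus X itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .matrices import BinaryMutationMatrix, CorrelationMatrix

__all__ = [
    "GeneClusterIndex",
    "build_rhd_clusters",
    "build_correlation_clusters",
    "build_cluster_index",
    "candidate_pool",
]


@dataclass(frozen=True)
class GeneClusterIndex:
    c1: Mapping[str, frozenset[str]]
    c2: Mapping[str, frozenset[str]]
    mu: float
    nu: float


def build_rhd_clusters(A: BinaryMutationMatrix, mu: float) -> dict[str, frozenset[str]]:
    """c1(g) = {h != g : RHD(g, h) >= mu} for every gene of A."""
    if not (0.0 <= mu <= 1.0):
        raise ValueError("mu must lie in [0, 1]")
    supports = A.support_sizes.astype(np.int64)
    if (supports == 0).any():
        empty = A.gene_ids[int(np.argmin(supports))]
        raise ValueError(f"gene {empty!r} has an empty support; filter the matrix first")
    b = A.values.astype(bool)
    overlap = b.T.astype(np.int64) @ b.astype(np.int64)
    rhd = (supports[:, None] - overlap) / supports[:, None]
    meets = rhd >= mu
    np.fill_diagonal(meets, False)
    return {
        g: frozenset(A.gene_ids[k] for k in np.flatnonzero(meets[j]))
        for j, g in enumerate(A.gene_ids)
    }


def build_correlation_clusters(W: CorrelationMatrix, nu: float) -> dict[str, frozenset[str]]:
    """c2(g) = {h != g : w(g, h) >= nu} for every gene of W."""
    if not (0.0 <= nu <= 1.0):
        raise ValueError("nu must lie in [0, 1]")
    meets = W.values >= nu
    np.fill_diagonal(meets, False)
    return {
        g: frozenset(W.gene_ids[k] for k in np.flatnonzero(meets[j]))
        for j, g in enumerate(W.gene_ids)
    }


def build_cluster_index(
    A: BinaryMutationMatrix, W: CorrelationMatrix, mu: float, nu: float
) -> GeneClusterIndex:
    """Build both cluster maps over A's gene universe."""
    return GeneClusterIndex(
        c1=build_rhd_clusters(A, mu),
        c2=build_correlation_clusters(W.reindex(A.gene_ids), nu),
        mu=mu,
        nu=nu,
    )


def candidate_pool(X: Iterable[str], index: GeneClusterIndex) -> frozenset[str]:
    """Genes eligible to extend the partial chromosome X.

    intersection of c1 over members of X, intersected with the union of c2
    over members, minus X itself.  An empty result is a valid signal that the
    partial set cannot be extended under (mu, nu).
    """
    members = list(X)
    if not members:
        raise ValueError("candidate pool of an empty partial chromosome is undefined")
    pool = frozenset.intersection(*(index.c1[g] for g in members))
    c2_union = frozenset.union(*(index.c2[g] for g in members))
    return (pool & c2_union) - frozenset(members)
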