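"""scikit-learn-style front end for the driver-pathway search."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .ga import GASettings, evolve
from .matrices import BinaryMutationMatrix, CorrelationMatrix

__all__ = ["SMCMNPathwayFinder"]


class SMCMNPathwayFinder(BaseEstimator):
    """Find a K-gene driver pathway maximizing coverage + exclusivity + connectivity.

    Parameters
    ----------
    K : int
        Number of genes in the pathway.
    pop_size : int or None
        Population size N; None means ceil(n_genes / 4).
    maxg, maxt : int
        Generation cap and early-stop patience (stagnant generations).
    rr : float
        Per-individual recombination probability per generation.
    mu, nu : float
        Cluster thresholds on relative Hamming distance and network weight.
    use_network : bool
        Include the network-connectivity term in the objective.
    random_state : int
        Seed for the run's random generator.

    Attributes
    ----------
    genes_ : tuple of str
        The best gene set found.
    score_ : GeneSetScore
        Its decomposed weight (coverage, mutual exclusivity, network, total).
    history_ : list of float
        Non-decreasing per-generation best fitness.
    n_generations_ : int
        Generations actually run.

    Examples
    --------
    >>> from smcmn.synthetic import generate_planted_dataset
    >>> inst = generate_planted_dataset()
    >>> finder = SMCMNPathwayFinder(K=3, random_state=0).fit(inst.A, inst.W)
    >>> sorted(finder.genes_) == sorted(inst.planted_genes)
    True
    """

    def __init__(
        self,
        K: int = 3,
        pop_size: int | None = None,
        maxg: int = 1000,
        maxt: int = 100,
        rr: float = 0.3,
        mu: float = 0.7,
        nu: float = 0.5,
        use_network: bool = True,
        random_state: int = 0,
    ) -> None:
        self.K = K
        self.pop_size = pop_size
        self.maxg = maxg
        self.maxt = maxt
        self.rr = rr
        self.mu = mu
        self.nu = nu
        self.use_network = use_network
        self.random_state = random_state

    def _settings(self) -> GASettings:
        return GASettings(
            K=self.K,
            pop_size=self.pop_size,
            maxg=self.maxg,
            maxt=self.maxt,
            rr=self.rr,
            mu=self.mu,
            nu=self.nu,
            seed=self.random_state,
            use_network=self.use_network,
        )

    @staticmethod
    def _coerce(X, W) -> tuple[BinaryMutationMatrix, CorrelationMatrix]:
        if not isinstance(X, BinaryMutationMatrix):
            arr = np.asarray(X)
            if arr.ndim != 2:
                raise ValueError("X must be a 2D samples x genes matrix")
            samples = [f"s{i + 1}" for i in range(arr.shape[0])]
            genes = [f"g{j + 1}" for j in range(arr.shape[1])]
            X = BinaryMutationMatrix(samples, genes, (arr != 0).astype(np.int8))
        if W is None:
            W = CorrelationMatrix(X.gene_ids, np.zeros((X.n_genes, X.n_genes)))
        elif not isinstance(W, CorrelationMatrix):
            W = CorrelationMatrix(X.gene_ids, np.asarray(W, dtype=float))
        return X, W

    def fit(self, X, W=None):
        """Run the search on mutation matrix ``X`` and network ``W``.

        ``X`` may be a BinaryMutationMatrix or a binary samples x genes array;
        ``W`` a CorrelationMatrix or a square symmetric array over X's genes
        (None means an empty network — the objective's network term is zero).
        """
        A, W = self._coerce(X, W)
        self._fitted_gene_index = {g: j for j, g in enumerate(A.gene_ids)}
        result = evolve(A, W, self._settings())
        self.genes_ = result.best.genes
        self.score_ = result.score
        self.history_ = result.history
        self.n_generations_ = result.generations_run
        self.result_ = result
        return self

    def transform(self, X):
        """Restrict a samples x genes matrix to the fitted pathway's columns."""
        if not hasattr(self, "genes_"):
            raise RuntimeError("fit must be called before transform")
        if isinstance(X, BinaryMutationMatrix):
            idx = [X.gene_index(g) for g in self.genes_]
            return X.values[:, idx]
        arr = np.asarray(X)
        # positional fallback assumes the same gene order as the fitted matrix
        idx = [self._fitted_gene_index[g] for g in self.genes_]
        return arr[:, idx]

    def fit_transform(self, X, W=None):
        return self.fit(X, W).transform(X)
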