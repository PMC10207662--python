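"""Clustering-seeded partheno-genetic search for the maximum-weight gene set.

A chromosome is a set of K distinct genes.  The population is seeded by a
two-step roulette construction restricted to the cluster-pruned candidate
pools, then evolved by fitness-proportional (roulette) selection with elitism
and a single-parent greedy drop-add recombination operator.  The loop stops at
``maxg`` generations, or earlier once the best fitness has stagnated for
``maxt`` consecutive generations.

All randomness flows from one seeded ``numpy.random.Generator`` owned by the
run, so identical settings and seed give identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .clustering import GeneClusterIndex, build_cluster_index, candidate_pool
from .matrices import BinaryMutationMatrix, CorrelationMatrix
from .scoring import GeneSetScore, SubsetScorer, smcmn_weight

__all__ = [
    "GASettings",
    "Chromosome",
    "EvolutionResult",
    "InfeasibleInstanceError",
    "init_chromosome",
    "init_population",
    "fitness",
    "select",
    "recombine",
    "evolve",
]


class InfeasibleInstanceError(RuntimeError):
    """No chromosome satisfying the cluster constraints could be constructed."""


@dataclass
class GASettings:
    """Tunables of the search.

    ``pop_size=None`` means the default N = ceil(|G| / 4).  ``mu`` thresholds
    the exclusivity (RHD) clusters, ``nu`` the network-weight clusters and the
    mean-correlation admission constraint; ``rr`` is the per-individual
    probability of undergoing recombination each generation; ``maxg`` caps the
    generations and ``maxt`` is the early-stop patience.
    """

    K: int = 3
    pop_size: int | None = None
    maxg: int = 1000
    maxt: int = 100
    rr: float = 0.3
    mu: float = 0.7
    nu: float = 0.5
    seed: int = 0
    use_network: bool = True
    max_init_retries: int = 100

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if self.pop_size is not None and self.pop_size < 2:
            raise ValueError("population size must be at least 2")
        for name in ("rr", "mu", "nu"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.maxg < 0 or self.maxt < 1:
            raise ValueError("maxg must be >= 0 and maxt >= 1")

    def effective_pop_size(self, n_genes: int) -> int:
        if self.pop_size is not None:
            return self.pop_size
        return max(2, int(np.ceil(n_genes / 4)))

    def as_dict(self) -> dict:
        return {
            "K": self.K,
            "pop_size": self.pop_size,
            "maxg": self.maxg,
            "maxt": self.maxt,
            "rr": self.rr,
            "mu": self.mu,
            "nu": self.nu,
            "seed": self.seed,
            "use_network": self.use_network,
        }


@dataclass(frozen=True)
class Chromosome:
    """An ordered set of K distinct gene identifiers with cached fitness."""

    genes: tuple[str, ...]
    fitness: float | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("chromosome genes must be distinct")


@dataclass
class EvolutionResult:
    best: Chromosome
    score: GeneSetScore
    generations_run: int
    history: list[float]
    settings: GASettings


def _roulette(candidates: Sequence[str], weights: np.ndarray, rng: np.random.Generator) -> str:
    total = float(weights.sum())
    if total <= 0:  # all-zero supports cannot happen post-filter; uniform fallback
        return candidates[int(rng.integers(len(candidates)))]
    return candidates[int(rng.choice(len(candidates), p=weights / total))]


def _mean_weight(W: CorrelationMatrix, gene: str, members: Sequence[str]) -> float:
    return sum(W.weight(gene, m) for m in members) / len(members)


def init_chromosome(
    A: BinaryMutationMatrix,
    W: CorrelationMatrix,
    index: GeneClusterIndex,
    settings: GASettings,
    rng: np.random.Generator,
) -> Chromosome | None:
    """Build one chromosome by the two-step roulette construction.

    The first gene is drawn with probability proportional to its support size;
    each subsequent gene is drawn the same way from the candidate pool of the
    partial set, restricted to candidates whose mean correlation with the
    current members is >= nu.  Returns None (a retryable failure, not an
    exception) when the pool empties or no candidate meets the constraint.
    """
    supports = A.support_sizes.astype(float)
    first = _roulette(A.gene_ids, supports, rng)
    members: list[str] = [first]
    while len(members) < settings.K:
        pool = candidate_pool(members, index)
        eligible = [
            g for g in sorted(pool) if _mean_weight(W, g, members) >= settings.nu
        ]
        if not eligible:
            return None
        w = np.array([supports[A.gene_index(g)] for g in eligible])
        members.append(_roulette(eligible, w, rng))
    return Chromosome(tuple(members))


def init_population(
    A: BinaryMutationMatrix,
    W: CorrelationMatrix,
    index: GeneClusterIndex,
    settings: GASettings,
    rng: np.random.Generator,
) -> list[Chromosome]:
    """N chromosomes built by retrying ``init_chromosome``; duplicates allowed."""
    n = settings.effective_pop_size(A.n_genes)
    population: list[Chromosome] = []
    consecutive_failures = 0
    budget = settings.max_init_retries * n
    while len(population) < n:
        chrom = init_chromosome(A, W, index, settings, rng)
        if chrom is None:
            consecutive_failures += 1
            if consecutive_failures >= budget:
                raise InfeasibleInstanceError(
                    f"could not build a feasible chromosome after {budget} consecutive "
                    f"attempts; consider lowering mu ({settings.mu}), nu ({settings.nu}) or K"
                )
            continue
        consecutive_failures = 0
        population.append(chrom)
    return population


def fitness(
    A: BinaryMutationMatrix,
    W: CorrelationMatrix | None,
    X: Chromosome,
    settings: GASettings,
) -> float:
    """Fitness(X) = W(M_X), the combined weight of the induced submatrix."""
    return smcmn_weight(A, W, X.genes, use_network=settings.use_network).total


def select(
    population: Sequence[Chromosome],
    best: Chromosome,
    rng: np.random.Generator,
) -> list[Chromosome]:
    """Roulette-wheel selection with elitism.

    N individuals are drawn with replacement with probability proportional to
    fitness, then the incumbent best replaces the first drawn slot so it is
    guaranteed to survive.  Population size is unchanged.
    """
    fits = np.array([c.fitness for c in population], dtype=float)
    if np.isnan(fits).any():
        raise ValueError("all fitness values must be computed before selection")
    probs = fits / fits.sum()
    drawn = rng.choice(len(population), size=len(population), replace=True, p=probs)
    out = [population[i] for i in drawn]
    out[0] = best
    return out


def recombine(
    X: Chromosome,
    A: BinaryMutationMatrix,
    W: CorrelationMatrix,
    index: GeneClusterIndex,
    settings: GASettings,
    rng: np.random.Generator,
) -> Chromosome:
    """Single-parent greedy drop-add recombination.

    With probability 1/2 the member with the smallest support is dropped,
    otherwise a uniformly random member.  The replacement pool is the
    intersection of the c1 clusters of the K-1 remaining genes (no c2 union
    here, unlike initialization); the candidate with the largest support whose
    mean correlation with the remaining genes is >= nu is added, ties broken
    toward the lexicographically smallest gene id.  If no candidate is
    eligible the chromosome is returned unchanged.
    """
    genes = list(X.genes)
    if rng.random() < 0.5:
        supports = [A.support_sizes[A.gene_index(g)] for g in genes]
        # ties on min support break toward the smallest gene id
        drop = min(zip(supports, genes))[1]
    else:
        drop = genes[int(rng.integers(len(genes)))]
    remaining = [g for g in genes if g != drop]
    pool = frozenset.intersection(*(index.c1[g] for g in remaining)) - set(remaining)
    best_gene: str | None = None
    best_support = -1
    for g in sorted(pool):
        if g == drop:
            continue
        if _mean_weight(W, g, remaining) < settings.nu:
            continue
        s = int(A.support_sizes[A.gene_index(g)])
        if s > best_support:
            best_gene, best_support = g, s
    if best_gene is None:
        return X
    return Chromosome(tuple(remaining) + (best_gene,))


def evolve(
    A: BinaryMutationMatrix,
    W: CorrelationMatrix,
    settings: GASettings,
    index: GeneClusterIndex | None = None,
) -> EvolutionResult:
    """Run the full search and return the elitist best gene set.

    Per generation: roulette selection (with the incumbent best pinned into
    slot 0), then each non-elite individual independently undergoes
    recombination with probability ``rr``.  The per-generation best fitness
    history is non-decreasing by elitism.
    """
    if settings.K > A.n_genes:
        raise ValueError(f"K={settings.K} exceeds the {A.n_genes} genes available")
    rng = np.random.default_rng(settings.seed)
    if index is None:
        index = build_cluster_index(A, W, settings.mu, settings.nu)
    scorer = SubsetScorer(A, W, use_network=settings.use_network)

    def scored(ch: Chromosome) -> Chromosome:
        if ch.fitness is not None:
            return ch
        return replace(ch, fitness=scorer.weight_of_genes(ch.genes))

    population = [scored(c) for c in init_population(A, W, index, settings, rng)]
    best = max(population, key=lambda c: c.fitness)
    history = [best.fitness]
    stagnant = 0
    generations = 0
    for _ in range(settings.maxg):
        generations += 1
        population = select(population, best, rng)
        for i in range(1, len(population)):
            if rng.random() < settings.rr:
                population[i] = scored(
                    recombine(population[i], A, W, index, settings, rng)
                )
        gen_best = max(population, key=lambda c: c.fitness)
        if gen_best.fitness > best.fitness:
            best = gen_best
            stagnant = 0
        else:
            stagnant += 1
        history.append(best.fitness)
        if stagnant >= settings.maxt:
            break
    score = smcmn_weight(A, W, best.genes, use_network=settings.use_network)
    return EvolutionResult(best, score, generations, history, settings)
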