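"""Synthetic test data: a small worked-example matrix and planted-pathway
instances with controllable coverage, exclusivity, background noise and
network structure.

These generators produce every input the test and acceptance suites consume;
no external download is required.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import (
    RAW_SCORE_MAX,
    BinaryMutationMatrix,
    CorrelationMatrix,
)

__all__ = [
    "PlantedParams",
    "PlantedInstance",
    "fixture_B",
    "generate_planted_dataset",
    "generate_random_instance",
    "write_dataset",
]


def fixture_B() -> BinaryMutationMatrix:
    """The 10-sample x 3-gene inclusion example.

    g2 mutates in samples 1-9 and its support contains the supports of g1
    (samples 1-2) and g3 (samples 3-4); sample 10 carries no mutation.  The
    set {g1, g2, g3} therefore has two inclusion relationships, relative
    Hamming distances RHD(g1,g2)=0, RHD(g2,g1)=7/9, RHD(g1,g3)=1, mutual
    exclusivity 16/27, and classical maximum-weight-submatrix score
    2*9 - (2+9+2) = 5.
    """
    values = np.zeros((10, 3), dtype=np.int8)
    values[0:2, 0] = 1  # g1: samples 1-2
    values[0:9, 1] = 1  # g2: samples 1-9
    values[2:4, 2] = 1  # g3: samples 3-4
    samples = [f"s{i}" for i in range(1, 11)]
    return BinaryMutationMatrix(samples, ["g1", "g2", "g3"], values)


@dataclass(frozen=True)
class PlantedParams:
    """Generator settings for a planted driver-pathway instance.

    Defaults describe a mid-sized cohort with one strong module: 200 samples,
    50 genes, a planted triple covering 60% of samples near-exclusively
    (2% pairwise co-mutation), 3% background mutation rate, strong network
    weight (0.9) inside the module against a weak background (uniform below
    0.3, i.e. below the default admission threshold nu = 0.5).
    """

    n_samples: int = 200
    n_genes: int = 50
    k_true: int = 3
    coverage_frac: float = 0.6
    overlap_rate: float = 0.02
    background_rate: float = 0.03
    within_weight: float = 0.9
    background_weight: float = 0.3
    seed: int = 7


@dataclass
class PlantedInstance:
    A: BinaryMutationMatrix
    W: CorrelationMatrix
    planted_genes: tuple[str, ...]
    params: PlantedParams


def _quantize(w: float) -> float:
    """Snap a weight onto the 0-999 raw-score grid so file round-trips are exact."""
    return round(w * RAW_SCORE_MAX) / RAW_SCORE_MAX


def generate_planted_dataset(
    params: PlantedParams | None = None, seed: int | None = None, **overrides
) -> PlantedInstance:
    """Generate a mutation matrix with one planted near-exclusive module.

    ``coverage_frac`` of the samples are assigned round-robin to the planted
    genes (balanced coverage); pairwise co-mutation is then injected within
    the module at ``overlap_rate`` per (covered sample, other planted gene).
    Background genes mutate independently at ``background_rate`` across all
    samples; planted genes carry no mutations outside the covered block, so
    with ``overlap_rate=0`` their supports are pairwise disjoint.  Network
    weights are ``within_weight`` between planted pairs and independent
    Uniform(0, background_weight) elsewhere, symmetric with zero diagonal,
    quantized to the 0-999 raw-score grid.
    """
    if params is None:
        params = PlantedParams(**overrides)
    elif overrides:
        raise TypeError("pass either a PlantedParams or keyword overrides, not both")
    if seed is not None:
        params = PlantedParams(**{**asdict(params), "seed": seed})
    p = params
    if p.k_true < 2:
        raise ValueError("k_true must be at least 2")
    n_covered = int(round(p.coverage_frac * p.n_samples))
    if n_covered < p.k_true:
        raise ValueError("coverage_frac * n_samples must be at least k_true")
    if p.k_true > p.n_genes:
        raise ValueError("k_true cannot exceed n_genes")

    rng = np.random.default_rng(p.seed)
    width = len(str(p.n_genes))
    gene_ids = [f"g{j + 1:0{width}d}" for j in range(p.n_genes)]
    sample_ids = [f"s{i + 1}" for i in range(p.n_samples)]
    planted_idx = np.sort(rng.choice(p.n_genes, size=p.k_true, replace=False))
    planted = tuple(gene_ids[j] for j in planted_idx)

    values = np.zeros((p.n_samples, p.n_genes), dtype=np.int8)
    covered = rng.choice(p.n_samples, size=n_covered, replace=False)
    # round-robin assignment balances coverage across the planted genes
    for pos, sample in enumerate(covered):
        values[sample, planted_idx[pos % p.k_true]] = 1
    if p.overlap_rate > 0:
        for sample in covered:
            for j in planted_idx:
                if values[sample, j] == 0 and rng.random() < p.overlap_rate:
                    values[sample, j] = 1
    background = np.setdiff1d(np.arange(p.n_genes), planted_idx)
    noise = rng.random((p.n_samples, len(background))) < p.background_rate
    values[:, background] = noise.astype(np.int8)

    w = np.zeros((p.n_genes, p.n_genes))
    for a in range(p.n_genes):
        for b in range(a + 1, p.n_genes):
            if a in planted_idx and b in planted_idx:
                val = _quantize(p.within_weight)
            else:
                val = _quantize(rng.uniform(0, p.background_weight))
            w[a, b] = w[b, a] = val

    A = BinaryMutationMatrix(sample_ids, gene_ids, values)
    W = CorrelationMatrix(gene_ids, w)
    return PlantedInstance(A, W, planted, p)


def generate_random_instance(
    n_samples: int = 40,
    n_genes: int = 12,
    mutation_rate: float = 0.2,
    seed: int = 0,
) -> tuple[BinaryMutationMatrix, CorrelationMatrix]:
    """An unstructured random instance (no planted signal) for oracle checks.

    Entries of A are independent Bernoulli(mutation_rate); genes that come out
    all-zero are re-drawn to mutate in one random sample so every support is
    nonempty.  Weights are Uniform(0, 1) on the raw-score grid.
    """
    rng = np.random.default_rng(seed)
    values = (rng.random((n_samples, n_genes)) < mutation_rate).astype(np.int8)
    for j in range(n_genes):
        if values[:, j].sum() == 0:
            values[int(rng.integers(n_samples)), j] = 1
    w = np.zeros((n_genes, n_genes))
    for a in range(n_genes):
        for b in range(a + 1, n_genes):
            w[a, b] = w[b, a] = _quantize(rng.uniform(0, 1))
    width = len(str(n_genes))
    gene_ids = [f"g{j + 1:0{width}d}" for j in range(n_genes)]
    sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    return BinaryMutationMatrix(sample_ids, gene_ids, values), CorrelationMatrix(gene_ids, w)


def write_dataset(instance: PlantedInstance, directory: str | Path) -> dict[str, Path]:
    """Write A.tsv, F.tsv, E.tsv and truth.json into ``directory``.

    Channel raw scores are reconstructed as round(w * 999) with the
    experimental channel equal to the literature one, so recombining the
    channels reproduces W exactly.  Zero-weight pairs are omitted from the
    edge lists.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    a_path = directory / "A.tsv"
    f_path = directory / "F.tsv"
    e_path = directory / "E.tsv"
    truth_path = directory / "truth.json"

    df = pd.DataFrame(
        instance.A.values, index=instance.A.sample_ids, columns=instance.A.gene_ids
    )
    df.to_csv(a_path, sep="\t", index_label="sample")

    genes = instance.W.gene_ids
    lines = []
    for a in range(len(genes)):
        for b in range(a + 1, len(genes)):
            raw = int(round(instance.W.values[a, b] * RAW_SCORE_MAX))
            if raw > 0:
                lines.append(f"{genes[a]}\t{genes[b]}\t{raw}")
    text = "\n".join(lines) + ("\n" if lines else "")
    f_path.write_text(text, encoding="utf-8")
    e_path.write_text(text, encoding="utf-8")

    truth_path.write_text(
        json.dumps(
            {"planted_genes": list(instance.planted_genes), "params": asdict(instance.params)},
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    return {"A": a_path, "F": f_path, "E": e_path, "truth": truth_path}
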