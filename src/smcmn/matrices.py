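"""Input matrices: somatic mutations, copy number, and gene-association networks.

The model consumes two objects: a binary mutation matrix ``A`` (samples x
genes) built from a somatic mutation matrix ``S`` and an optional copy-number
matrix ``C``, and a symmetric gene-gene correlation matrix ``W`` in [0, 1]
built from two STRING-style association channels (a literature channel ``F``
and an experimental channel ``E``, raw scores 0-999).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SomaticMatrix",
    "CopyNumberMatrix",
    "BinaryMutationMatrix",
    "AssociationChannel",
    "CorrelationMatrix",
    "MatrixFormatError",
    "read_mutation_matrix",
    "read_association_channel",
    "build_binary_matrix",
    "normalize_scores",
    "combine_correlation",
    "filter_low_frequency_genes",
]

RAW_SCORE_MAX = 999


class MatrixFormatError(ValueError):
    """Raised when an input file violates the expected format or domain."""


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise MatrixFormatError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)
    return ids


@dataclass
class _SampleGeneMatrix:
    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    _allowed: frozenset = field(default=frozenset({0, 1}), repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise MatrixFormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        bad = ~np.isin(self.values, list(self._allowed))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise MatrixFormatError(
                f"entry {int(self.values[i, j])} at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r} is outside the allowed set "
                f"{sorted(self._allowed)}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class SomaticMatrix(_SampleGeneMatrix):
    """Samples x genes somatic mutation indicator matrix, entries in {0, 1}."""

    _allowed: frozenset = field(default=frozenset({0, 1}), repr=False)


@dataclass
class CopyNumberMatrix(_SampleGeneMatrix):
    """Samples x genes copy-number call matrix, entries in {-1, 0, 1}.

    A nonzero entry marks the gene as lying in a statistically significant
    amplification (+1) or deletion (-1) region of that sample.
    """

    _allowed: frozenset = field(default=frozenset({-1, 0, 1}), repr=False)


@dataclass
class BinaryMutationMatrix(_SampleGeneMatrix):
    """The binary alteration matrix A the model scores.

    ``a_ij = 1`` when gene j carries any alteration (point mutation or
    copy-number event) in sample i.  ``support(g)`` is the set of sample
    indices in which gene g is altered (written Gamma(g) in the model).
    """

    _allowed: frozenset = field(default=frozenset({0, 1}), repr=False)

    def __post_init__(self) -> None:
        super().__post_init__()
        self._gene_index = {g: j for j, g in enumerate(self.gene_ids)}

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not present in the mutation matrix") from None

    def support(self, gene: str) -> frozenset[int]:
        j = self.gene_index(gene)
        return frozenset(np.flatnonzero(self.values[:, j]).tolist())

    @property
    def support_sizes(self) -> np.ndarray:
        """Per-gene |Gamma(g)|, aligned with ``gene_ids``."""
        return self.values.sum(axis=0)


@dataclass
class AssociationChannel:
    """One STRING-style association channel: unordered gene pair -> raw score.

    Raw scores are integers in [0, 999]; self-pairs are rejected.
    """

    edges: dict[frozenset, int]

    def __post_init__(self) -> None:
        for pair, raw in self.edges.items():
            if len(pair) != 2:
                raise MatrixFormatError(f"self-association not allowed: {set(pair)}")
            if not (0 <= raw <= RAW_SCORE_MAX):
                a, b = sorted(pair)
                raise MatrixFormatError(
                    f"raw score {raw} for pair ({a}, {b}) outside [0, {RAW_SCORE_MAX}]"
                )

    def normalized(self) -> dict[frozenset, float]:
        """Scores mapped onto [0, 1] by dividing by the channel maximum 999."""
        return {pair: normalize_scores(raw) for pair, raw in self.edges.items()}


@dataclass
class CorrelationMatrix:
    """Symmetric gene x gene weights in [0, 1] with zero diagonal (the W matrix)."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise MatrixFormatError("correlation matrix must be square over gene_ids")
        if not np.allclose(self.values, self.values.T):
            raise MatrixFormatError("correlation matrix must be symmetric")
        if np.diag(self.values).any():
            raise MatrixFormatError("correlation matrix must have a zero diagonal")
        if self.values.min() < 0 or self.values.max() > 1:
            raise MatrixFormatError("correlation weights must lie in [0, 1]")
        self._gene_index = {g: j for j, g in enumerate(self.gene_ids)}

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not present in the correlation matrix") from None

    def weight(self, gene_a: str, gene_b: str) -> float:
        return float(self.values[self.gene_index(gene_a), self.gene_index(gene_b)])

    def reindex(self, gene_ids: Sequence[str]) -> "CorrelationMatrix":
        """Restrict/expand to ``gene_ids``; genes absent here get all-zero rows."""
        n = len(gene_ids)
        out = np.zeros((n, n))
        pos = {g: i for i, g in enumerate(gene_ids)}
        common = [g for g in gene_ids if g in self._gene_index]
        src = np.array([self._gene_index[g] for g in common], dtype=int)
        dst = np.array([pos[g] for g in common], dtype=int)
        if len(common):
            out[np.ix_(dst, dst)] = self.values[np.ix_(src, src)]
        return CorrelationMatrix(list(gene_ids), out)


# ---------------------------------------------------------------------------
# readers


def read_mutation_matrix(path: str | Path, kind: str = "somatic"):
    """Read a samples x genes TSV (gene-symbol header, sample-ID first column).

    Parameters
    ----------
    path : file path
    kind : {"somatic", "cnv"}
        "somatic" admits entries {0, 1}; "cnv" admits {-1, 0, 1}.
    """
    if kind not in ("somatic", "cnv"):
        raise ValueError(f"kind must be 'somatic' or 'cnv', got {kind!r}")
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: non-numeric entry ({exc})") from None
    if values.size and not np.equal(values, np.round(values)).all():
        raise MatrixFormatError(f"{path}: non-integer entry found")
    cls = SomaticMatrix if kind == "somatic" else CopyNumberMatrix
    try:
        return cls(list(df.index), list(df.columns), values.astype(np.int8))
    except MatrixFormatError as exc:
        raise MatrixFormatError(f"{path}: {exc}") from None


def read_association_channel(path: str | Path) -> AssociationChannel:
    """Read a 3-column edge list ``geneA<TAB>geneB<TAB>raw_score``.

    Duplicate (unordered) pairs are a format error rather than last-write-wins.
    """
    edges: dict[frozenset, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise MatrixFormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            a, b, raw_s = parts
            if a == b:
                raise MatrixFormatError(f"{path}:{lineno}: self-pair {a!r}")
            try:
                raw = int(raw_s)
            except ValueError:
                raise MatrixFormatError(f"{path}:{lineno}: non-integer score {raw_s!r}") from None
            pair = frozenset((a, b))
            if pair in edges:
                raise MatrixFormatError(f"{path}:{lineno}: duplicate pair ({a}, {b})")
            if not (0 <= raw <= RAW_SCORE_MAX):
                raise MatrixFormatError(f"{path}:{lineno}: score {raw} outside [0, {RAW_SCORE_MAX}]")
            edges[pair] = raw
    return AssociationChannel(edges)


# ---------------------------------------------------------------------------
# constructors


def build_binary_matrix(
    S: SomaticMatrix, C: CopyNumberMatrix | None = None
) -> BinaryMutationMatrix:
    """Fuse point mutations and copy-number calls into the binary matrix A.

    ``a_ij = 1`` iff s_ij != 0 or c_ij != 0 — a gene counts as altered when
    either channel reports an event.  When ``C`` is absent, A is S.  S and C
    are aligned on the intersection of their sample and gene universes, in S's
    order.
    """
    if C is None:
        return BinaryMutationMatrix(S.sample_ids, S.gene_ids, (S.values != 0).astype(np.int8))
    genes = [g for g in S.gene_ids if g in set(C.gene_ids)]
    samples = [p for p in S.sample_ids if p in set(C.sample_ids)]
    if not genes:
        raise MatrixFormatError("somatic and copy-number matrices share no genes")
    if not samples:
        raise MatrixFormatError("somatic and copy-number matrices share no samples")
    s_df = pd.DataFrame(S.values, index=S.sample_ids, columns=S.gene_ids)
    c_df = pd.DataFrame(C.values, index=C.sample_ids, columns=C.gene_ids)
    s = s_df.loc[samples, genes].to_numpy()
    c = c_df.loc[samples, genes].to_numpy()
    return BinaryMutationMatrix(samples, genes, ((s != 0) | (c != 0)).astype(np.int8))


def normalize_scores(raw: int | np.ndarray) -> float | np.ndarray:
    """Map a raw channel score in [0, 999] onto [0, 1] (divide by 999)."""
    arr = np.asarray(raw)
    if (arr < 0).any() or (arr > RAW_SCORE_MAX).any():
        raise ValueError(f"raw score outside [0, {RAW_SCORE_MAX}]")
    out = arr / RAW_SCORE_MAX
    return float(out) if np.isscalar(raw) or arr.ndim == 0 else out


def combine_correlation(
    F: AssociationChannel, E: AssociationChannel, gene_ids: Sequence[str]
) -> CorrelationMatrix:
    """Combine the literature (F) and experimental (E) channels into W.

    ``w_ij = max(f_ij, e_ij)`` when the experimental channel is nonzero, else
    0: a literature association only counts when some experimental evidence
    backs it.  Pairs absent from both channels get 0; genes absent from the
    network keep all-zero rows.
    """
    gene_ids = list(gene_ids)
    pos = {g: i for i, g in enumerate(gene_ids)}
    f_norm = F.normalized()
    e_norm = E.normalized()
    n = len(gene_ids)
    w = np.zeros((n, n))
    for pair, e in e_norm.items():
        if e == 0:
            continue
        a, b = tuple(pair)
        if a not in pos or b not in pos:
            continue
        val = max(f_norm.get(pair, 0.0), e)
        if not (0.0 <= val <= 1.0):
            raise MatrixFormatError(f"combined weight {val} outside [0, 1]")
        i, j = pos[a], pos[b]
        w[i, j] = w[j, i] = val
    return CorrelationMatrix(gene_ids, w)


def filter_low_frequency_genes(
    A: BinaryMutationMatrix, min_frac: float = 0.005
) -> BinaryMutationMatrix:
    """Drop genes mutated in fewer than ``min_frac`` of samples.

    The boundary is strict: a gene mutated in exactly ``min_frac`` of samples
    is retained.  The sample set is unchanged.
    """
    if not (0.0 <= min_frac <= 1.0):
        raise ValueError("min_frac must lie in [0, 1]")
    frac = A.support_sizes / A.n_samples
    keep = frac >= min_frac
    if not keep.any():
        raise ValueError("frequency filter removed every gene")
    genes = [g for g, k in zip(A.gene_ids, keep) if k]
    return BinaryMutationMatrix(A.sample_ids, genes, A.values[:, keep])
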