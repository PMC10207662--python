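# Methods

## Model

`smcmn` scores a gene set *M* of size *K* in a binary mutation matrix
*A* (|P| samples × |G| genes) and a correlation matrix *W* by

    W(M) = CO(M) + ME(M) + N(M)

with no per-term weights. The three terms:

* **Coverage.** `CO(M) = |Γ(M)| / max_{g∈G} |Γ(g)|`, where Γ(g) is the set of
  samples in which g is altered and Γ(M) their union over the set. The
  denominator is the largest single-gene support over the **whole post-filter
  gene universe**, not just the set, so CO depends on genes outside M and can
  exceed 1. This normalization makes "coverage" mean "how much better than the
  best single gene".
* **Mutual exclusivity.** The relative Hamming distance
  `RHD(g, h) = |Γ(g) \ Γ(h)| / |Γ(g)|` is asymmetric: it is 0 exactly when
  Γ(g) ⊆ Γ(h) (an *inclusion relationship*) and 1 exactly when the supports
  are disjoint. `RHD(g, M)` averages g's distance to the K−1 other members and
  `ME(M)` averages that over members; equivalently, ME is the mean of all
  K(K−1) ordered pairwise distances. Classical coverage−overlap scores such as
  `2|Γ(M)| − Σ|Γ(g)|` cannot distinguish a set with inclusions from a
  genuinely exclusive one with the same counts; ME can, which is the point of
  the measure.
* **Network connectivity.** `N(M)` is the sum of the ordered off-diagonal
  entries of the submatrix of W over M, divided by |M|·(|M|−1) — i.e. the mean
  pairwise association weight; in [0, 1].

ME is an **error** for genes with empty support rather than a silent 0: such
genes cannot survive the frequency filter, so their appearance indicates the
filter was skipped.

## Input construction

* Binary matrix: `a_ij = 1` iff the SNV entry or the copy-number entry is
  nonzero. The inclusive-OR reading is the standard SNV ∪ CNA integration; an
  AND would zero out genes lacking copy-number calls. Without a copy-number
  matrix, A is the SNV matrix itself.
* Correlation matrix: channel scores (integers 0–999) are normalized by the
  channel maximum 999; `w = max(f, e)` when the experimental channel e is
  nonzero, else 0 — literature evidence only counts when some experimental
  evidence corroborates the pair. The diagonal is forced to 0 so N(M) averages
  off-diagonal pairs only. Genes absent from the network files keep all-zero
  rows (they are not dropped). Duplicate edges in a channel file are treated
  as a format error, not merged.
* Frequency filter: genes mutated in fewer than 0.5% of samples are dropped
  (strict inequality: exactly 0.5% is retained).

## Search

A chromosome is a set of K distinct genes. Preprocessing builds two clusters
per gene: `c1(g) = {h : RHD(g, h) ≥ μ}` (RHD taken in the asymmetric
direction from the cluster owner toward the candidate, exactly as the model
defines it) and `c2(g) = {h : w(g, h) ≥ ν}`.

* **Initialization.** First gene: roulette with probability ∝ |Γ(g)|.
  Each next gene: roulette over the pool `⋂ c1 ∩ ⋃ c2` of the current
  members (minus the members themselves), restricted to candidates whose mean
  correlation with the members is ≥ ν. An empty pool is a retryable failure;
  a population of N chromosomes is built with retries, and persistent failure
  raises an error suggesting smaller μ/ν/K.
* **Selection.** Fitness-proportional sampling with replacement (fitness is
  W(M), always > 0 since CO > 0), with the incumbent best individual pinned
  into the first slot (elitism), so best fitness is non-decreasing.
* **Recombination** (single-parent, applied to each non-elite individual with
  probability `rr` per generation): drop the minimum-support member or a
  uniformly random member (unweighted coin flip); the replacement pool is
  `⋂ c1` over the K−1 remaining genes — deliberately *without* the c2 union,
  mirroring the asymmetry between initialization and recombination; add the
  eligible candidate (mean correlation with the remaining genes ≥ ν, with
  denominator k = K−1, the post-drop size) of largest support, ties broken
  toward the lexicographically smallest gene id for reproducibility. With no
  eligible candidate the chromosome is unchanged.
* **Termination.** Hard cap `maxg` generations, early stop after `maxt`
  consecutive generations without improvement of the best fitness. `maxg = 0`
  returns the best of the initial population.

All randomness flows from one `numpy.random.Generator` seeded by the run, so
identical settings and seed reproduce the result exactly.

### Defaults

| parameter | default | meaning |
|---|---|---|
| N | ⌈\|G\|/4⌉ (min 2) | population size |
| maxg | 1000 | generation cap |
| maxt | 100 | early-stop patience (stagnant generations) |
| rr | 0.3 | per-individual recombination probability |
| μ | 0.7 | RHD cluster threshold |
| ν | 0.5 | network cluster / admission threshold |

`rr` is interpreted as the per-individual recombination probability (the
standard recombination rate of a partheno-genetic algorithm) and `maxt` as
stagnation patience; both interpretations are design choices where the
operator definitions leave room.

## Significance

For an identified set of size K, `random_test` draws `n_draws` (default 1000)
uniform K-subsets of the post-filter gene universe — no connectivity or
cluster constraint — scores each with the same objective (including the
network term if it was used for the search), and reports
`p = #{draws with weight strictly greater than observed} / n_draws`. Ties do
not count against the observed set; resolution is 1/n_draws. Under the null
(the observed set itself drawn uniformly) the p-value is approximately
uniform, which the test suite checks via its mean over replicates.

## Synthetic data

The generator plants one K_true-gene module: a fraction `coverage_frac` of
samples is assigned round-robin to the planted genes (balancing coverage
across them), pairwise co-mutation is injected at `overlap_rate` per covered
sample and other planted gene, and background genes mutate independently at
`background_rate` across all samples. Planted genes carry no mutations outside
the covered block, so `overlap_rate = 0` yields pairwise-disjoint supports and
ME = 1 by construction. Network weights are `within_weight` (default 0.9) for
planted pairs and Uniform(0, `background_weight` = 0.3) elsewhere — below the
default admission threshold ν = 0.5, so the network channel genuinely
separates module from background. Weights are quantized to the 0–999 integer
grid at generation time, which makes the TSV round-trip (write channels as
`round(w·999)`, read back, recombine) exact rather than approximate.

Defaults: 200 samples, 50 genes, K_true = 3, coverage 0.6, overlap 0.02,
background 0.03, seed 7.

What the generator does **not** emulate: real mutation-rate heterogeneity
across samples and genes (hypermutators, long genes), multiple overlapping
pathways, subtype structure, or realistic protein-interaction topology
(degree distribution, hubs). Passing the recovery tests therefore shows the
search and score behave correctly under the model's own assumptions, not that
the method's biological findings on tumor cohorts are reproduced.

A second generator, `generate_random_instance`, produces unstructured
Bernoulli matrices with uniform network weights for property tests and
permutation-test calibration (genes that come out empty are re-drawn to
mutate in one sample so every support is nonempty).

## Oracle experiments and problem sizes

* **Worked example.** A 10 × 3 matrix with two inclusion relationships is the
  exact-arithmetic regression anchor (all pairwise and gene-to-set distances,
  ME = 16/27, classical weight 5).
* **Exhaustive equivalence.** The search is compared against brute force over
  all C(|G|, 3) subsets on 20 seeded 12-gene, 40-sample planted instances
  (background rate 0.1 so background genes stay observable at that scale).
  The planted family is used deliberately: its modules satisfy the cluster
  thresholds by construction, so the pruned search space provably contains
  the global optimum and the unconstrained exhaustive oracle is the search's
  true target. On unstructured uniform instances the unconstrained optimum
  frequently violates the μ/ν constraints, making that comparison ill-posed
  — it would measure the pruning heuristic's assumptions, not the search's
  correctness.
* **Planted recovery.** Full generator defaults (200 × 50, K = 3), ten run
  seeds, plus a 1000-draw permutation test of the planted triple.
* **Null calibration.** 200 replicates of the permutation test at 200 draws
  each on a 30 × 15 instance; the mean p-value must lie in [0.40, 0.60].

These sizes keep the whole suite fast while leaving each check statistically
meaningful.

## Numerical and degenerate-input choices

* All score identities are exact rational arithmetic in floating point;
  component/total consistency is asserted to 1e−12.
* The fast subset scorer used by the search and the permutation test
  precomputes pairwise exclusive-support counts (`|Γ(g) \ Γ(h)|`) once per
  matrix; its agreement with the definitional functions is property-tested.
* K < 2, empty gene sets, empty supports, K > |G|, and an all-genes-filtered
  matrix are errors with descriptive messages, not silent results.
* Chromosome distinctness (K distinct genes) is enforced by the type itself.

## Known limitations

* The greedy add step of recombination is deterministic given the pool, so
  population diversity comes mainly from initialization and the stochastic
  drop; on instances whose optimum lies outside the cluster-pruned space the
  search cannot reach it by design (the clusters are the method's speed/
  completeness trade-off).
* Coverage's global denominator means scores are not comparable across
  datasets with different maximal gene supports.
* The permutation null ignores gene-level mutation-rate heterogeneity; its
  p-values are calibrated against uniform gene sampling only.
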