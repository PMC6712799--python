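# Methods

## Problem and model

A case-control genotype table holds m samples over n SNPs coded
0 (common homozygote), 1 (heterozygote), 2 (rare homozygote), with a
binary phenotype (`Class`, 1 = case).  Epistatic loci are loci whose
joint genotype predicts the phenotype even though each locus alone does
not.  `epitabu` models SNPs and phenotype as nodes of a discrete
Bayesian network — a DAG plus conditional probability tables — and
scores candidate structures with the decomposable BIC

    BIC(G | D) = Σᵢ Σⱼ Σₖ m_ijk log(m_ijk / m_ij·) − Σᵢ qᵢ(rᵢ−1)/2 · log m.

Cells with m_ijk = 0 contribute zero to the likelihood sum (limit
convention).  The logarithm base is configurable and defaults to the
natural log; the base rescales all entropies and scores uniformly and
never changes any ranking, but absolute MI thresholds quoted in nats do
not transfer to bits.

Per-node sufficient statistics are computed sparsely: parent
combinations are indexed in mixed radix with the lowest parent index as
the fastest-varying digit, and only combinations observed in the data
are materialized, while qᵢ enters the penalty exactly.  A node with an
absurdly large parent set therefore scores (very poorly) in O(m) rather
than exhausting memory; a configurable cap (default 3²⁵ combinations)
still guards against pathological requests.

## Bitwise screening

Genotypes are encoded per SNP as three indicator bitstrings (one per
genotype value), the phenotype as two; the first sample occupies the
most significant bit, so a column read top to bottom prints as the
bitstring reads left to right.  Any joint probability is then
popcount(AND of the selected bitstrings) / m with maximum-likelihood
plug-in frequencies and no pseudocounts.  The conditional mutual
information

    I(Class | SNP₁..SNPₖ) = H(Class) + H(SNP₁..SNPₖ) − H(Class, SNP₁..SNPₖ)

is computed this way for all C(n, k) combinations (k capped at 3, the
orders the detector targets) and ranked descending, ties broken by
lexicographic index order.  Tiny negative MI from rounding (> −10⁻¹²)
is clamped to zero; anything more negative raises, as it would indicate
a counting bug.

## Seed network

The top-N ranked pairs (default N = 5) seed the network.  Orientation
places the phenotype as a *root*: Class → SNP edges plus, for each
top-N pair, a lower-index → higher-index SNP edge as the explicit
interaction hypothesis.  SNPs missing from the top-N are covered by
their first-appearing pair in the remainder of the ranking, which
contributes Class → SNP edges only: a low-MI coverage pair carries no
evidence of interaction, and its SNP–SNP edge would only inflate parent
sets.  The root orientation is essential, not cosmetic: with the
phenotype as a sink the class node would collect one parent per covered
SNP, its qᵢ = 3ⁿ would turn the BIC into a pure penalty (each sample
its own parent configuration, likelihood exactly zero) and the early
search would degenerate into blind penalty pruning that loses the
planted edges.

## Genetic-tabu search

- **Initial population.**  Chained single-edge edits (add / drop /
  reverse, each rejected if it would create a cycle) grow the seed into
  `population_size` individuals.
- **Selection.**  Roulette with Pᵢ = fᵢ / Σ fᵢ.  Raw BIC is negative,
  so fitness is shifted: fᵢ = BICᵢ − min(BIC) + δ with δ = 1, which
  preserves ranking, guarantees positivity, and degenerates to uniform
  sampling when all scores are equal.
- **Crossover.**  Two columns (parent sets of two nodes) are chosen and
  exchanged between the two parents row by row; a row whose exchange
  would close a ring in either offspring-in-progress is skipped.
  Exchanging at the same node index in both parents keeps node identity
  intact and makes crossover of identical parents the identity.  A tabu
  list of adjacency fingerprints (bounded FIFO, exact-equality
  membership, capacity `tabu_length`) rejects offspring already seen;
  the exchange is retried up to 10 times (the unbounded loop the
  operator suggests cannot guarantee termination), then the last
  offspring are returned flagged and left unrecorded.
- **Mutation.**  Each individual flips Binomial(n(n−1), P_m) uniformly
  chosen off-diagonal entries per generation — the mutation probability
  applies per locus of the chromosome, the standard GA convention,
  giving ≈ 0.8 flip attempts per individual at the default P_m = 0.002.
  A mutant is accepted only if acyclic, fitness-improving and absent
  from a second tabu list; fitness-degrading mutants are recorded there
  so the search does not revisit them.  (A per-individual reading of
  P_m would yield ~0.1 attempts per generation across the whole
  population, leaving the operator without any effect.)
- **Elitism.**  The best-ever individual is tracked outside the
  population and also re-injected into one slot of each new generation;
  without re-injection, likelihood-carrying edges drift out of the
  breeding pool on a measurable fraction of runs.
- **Termination.**  The run stops at `max_iterations` (60), when
  neither the best nor the population-mean fitness has improved for
  `stagnation_k` (3) consecutive generations, or at an optional fitness
  threshold (disabled by default; no principled universal value exists).

Defaults (population 50, crossover 0.7, mutation 0.002, tabu length 30,
60 iterations, stagnation 3) are the published configuration.  A single
seeded NumPy generator drives every stochastic step, so identical seed,
data and configuration reproduce identical histories bit for bit.

## Reading pairs off the network

The default extraction reports every unordered SNP pair inside the
**Markov blanket** of the phenotype node (parents, children, and
co-parents of children), annotated with I(Class | SNP₁, SNP₂) recomputed
from the bit matrix and sorted descending.  The blanket matters under
case-control ascertainment: sampling equal cases and controls from a
prevalence-K population induces dependence between interacting loci, so
the best-scoring representation of a purely epistatic pair is the
collider Class → SNP₁ ← SNP₂ — the partner SNP is informative but not
adjacent to the phenotype node, and an adjacency-only rule misses it.
Rules `adjacent`, `parents` and `snp-edge` are selectable for stricter
readings.  Detection accuracy over a batch is the fraction of datasets
whose full planted SNP set appears as one reported tuple (optionally
within the top-M entries); requiring the exact tuple, not merely both
names separately, is the stricter, unambiguous reading.

For large inputs a per-SNP χ² prefilter (3 genotypes × 2 classes, no
continuity correction, unobserved genotype rows dropped from the table)
reduces the SNP set before pair ranking; the default keeps SNPs with
p < 0.01.  Constant SNPs are untestable and always dropped with a
warning.

## Simulator

A k-locus penetrance model (k = 2 or 3) is a 3ᵏ table of
P(case | genotype combination) constrained so that every locus's
Hardy–Weinberg-weighted marginal penetrance equals the prevalence K
(within 10⁻⁶) — no main effects — with heritability defined on the
penetrance scale as

    h² = Σ_g f_g (P_g − K)² / (K(1−K)),

f_g the Hardy–Weinberg frequency of combination g.  Construction is a
random search over deviation directions in the polytope {zero weighted
marginals, penetrances in [0, 1]}: Gaussian tables projected onto the
marginal constraint alternate with polytope vertices obtained by
maximizing random linear objectives (vertices attain the largest
feasible variance).  A direction is scaled to the exact target variance
when that fits the box; when the target lies just above a direction's
ceiling, the ceiling is accepted provided the achieved h² stays within
5 % relative of target.  The combination h² = 0.4, MAF = 0.4, K = 0.2
sits exactly in this regime: the feasible maximum is h² = 0.3844
(verified by LP vertex enumeration), inside the 5 % band, so the
generator runs at the feasibility ceiling there.  Genuinely
unreachable settings (for example h² = 0.9 at MAF = 0.05) raise an
explicit infeasibility error.

Datasets draw functional genotypes from Hardy–Weinberg equilibrium at
the model MAF, assign status from the penetrance table, and
rejection-sample until the case and control quotas are met (balanced
400/400 by default).  Noise SNPs are drawn independently of status with
MAFs uniform in (0.05, 0.5); planted column positions and sample rows
are shuffled.  Batch generation uses per-file seeds base + i and writes
a JSON manifest mapping each file to its truth SNPs.

Desk-scale defaults never published with the original experiments —
20 SNPs per file, 400 cases/400 controls, prevalence 0.2 — were chosen
once as realistic GAMETES-style conditions and are exposed as flags.

What the simulator does *not* emulate: linkage disequilibrium between
SNPs, genotyping error, missing genotypes, covariates, and population
structure.  Passing the recovery tests therefore demonstrates that the
search machinery finds planted pure interactions under idealized
sampling, not that real GWAS cohorts behave this way.

## Numerical and design notes

- Cycle machinery: full Kahn topological sort for validation,
  depth-first reachability for single-edge queries; self-loops count as
  cycles by convention.
- Score caching: node terms are memoized by (node, parent set) per
  dataset, so populations that share most families re-score only the
  edited columns.
- χ² prefilter direction is exposed (`keep_below`): keeping the
  *significant* SNPs is the default, the useful direction for screening
  before interaction search.
- Edges out of the Class node are legal throughout the search (the root
  orientation relies on them); no structural prior is used.
- The mutation tabu list is separate from the crossover tabu list but
  shares the capacity policy.
- MI is reported in nats by default; rankings are base-invariant.

## Limitations

- Exhaustive pair ranking is O(n²) MI evaluations; beyond a few
  thousand SNPs the χ² prefilter is required (the ranking refuses
  budgets above 2·10⁶ combinations by default).
- Detection of k = 3 interactions is supported by the information
  machinery but the end-to-end pipeline is tuned and validated for
  pairs.
- BIC with plug-in frequencies is consistent but conservative at small
  m; no small-sample entropy bias correction is applied.
- The GA is stochastic; accuracy guarantees are statistical, under the
  simulator's idealized conditions, not per-run certainties.
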