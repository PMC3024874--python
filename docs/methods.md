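# Methods

## Position encoding

A formula is an ordered herb list; order carries meaning (the
Master–Adviser–Soldier–Guide convention places more central herbs earlier).
The corpus is encoded as an integer position matrix *A* (1-based listing
position, 0 = absent) and the normalised matrix *B = A/k* row-wise, so each
formula's entries are exactly {1/k, 2/k, …, 1} regardless of its length.
Herb ids are assigned in first-appearance order, which makes the encoding a
pure function of the input file.  A herb repeated within one raw formula
makes *A* ill-defined, so loading rejects it by default; with `dedupe=True`
the first (most central) occurrence is kept.  Synonym normalisation follows
mapping chains (cycles are an error) and, where merging creates a
within-formula duplicate, keeps the earliest position and compacts the rest.
`B` is stored as floating point; since k rarely exceeds ~50, comparisons in
tests use an absolute tolerance of 1e-12.

## Pair scoring

For each unordered pair the package computes presence frequencies P(x),
P(y), P(x,y) over the m formulae, mutual information, the mean
between-herb-distance d̄, the combined score, and a Pearson χ² independence
test.

**Mutual information.**  The default `pmi` form is the joint-weighted
pointwise mutual information P(xy)·log₂(P(xy)/(P(x)P(y))) with the limit
convention MI = 0 at P(xy) = 0.  It is zero exactly at independence,
positive under co-occurrence enrichment, and — unlike the full 2×2 mutual
information, which is also offered (`mi_form="joint2x2"`) — it is *small*
under anti-correlation, matching the intended reading that a large value
means a strong positive association.  The log base is 2 (bits); any base
change rescales all scores uniformly and cannot alter ranks.

**Distance.**  d(x,y,i) = |b_ix − b_iy| is defined only where both herbs
occur, so d̄ averages over exactly the n_xy co-occurring formulae
(denominator n_xy).  d̄ is always positive (positions within a formula are
distinct), so the ratio score is finite.

**Score.**  S = MI/d̄ is the simplest composition that is strictly
increasing in MI at fixed d̄ and strictly decreasing in d̄ at fixed MI.
The alternative S = MI·(1 − d̄) (`score_form="complement"`) satisfies the
same monotonicity with a gentler distance penalty; every output records
which form produced it.  Pairs co-occurring fewer than `min_cooccur` times
(default 3) are reported as filtered rather than scored: a single
co-occurrence yields an unstable d̄ and a noisy MI, and such pairs would
otherwise litter the top of the ranking.

**χ².**  The independence test is the textbook Pearson statistic
m(ad − bc)²/(r₁r₂c₁c₂) on the 2×2 presence/absence table, 1 df, no
continuity correction.  A zero margin (e.g. a herb present in every
formula) leaves the test undefined; the implementation returns p = 1 with a
`degenerate` flag rather than guessing.

**Ranking.**  Sorted by score descending with deterministic tie-breaks
(smaller d̄, then lexicographic names), so identical inputs always give
identical rankings.

## Herb network and hub module

The herb network takes the top-N ranked pairs (default 100) as weighted
edges; by construction the top-n₁ network is an edge-subgraph of the
top-n₂ network for n₁ ≤ n₂.  The hub module extends a hub herb set to all
pairs significant at α (default 0.05, raw p per pair; a Benjamini–Hochberg
option exists and is recorded in the output metadata) that touch a hub,
plus significant pairs among the resulting neighbour set — one-hop closure
only, which keeps the module interpretable as "herbs tied to the hubs".
Significance is strict (p < α), so the module never contains an edge at or
above the threshold.  Recovery against a curated reference pair list is
reported as precision over the ranked edges (per-k precision included);
reference herbs that never appear in the network are ignored, since the
comparison is over edges, not nodes.

## Co-module analysis

**Enrichment** is the one-sided Fisher exact test (hypergeometric upper
tail) of a gene set against each pathway within a user-supplied background
universe, with Benjamini–Hochberg FDR across the tested pathways.  BH
adjusted values are never below the raw p and are monotone in the raw-p
ranking.

**Closeness** is the mean unweighted shortest-path length over all
cross pairs (a, b), a ≠ b, between two gene sets on the interaction
network.  Disconnected pairs are excluded from the mean — assigning them an
arbitrary large distance would make the statistic depend on that arbitrary
choice — and the covered-pair fraction is reported alongside so that
exclusion is visible.  Self-pairs (a gene in both sets) are excluded to
avoid trivially deflating the mean with zeros.  The permutation null keeps
the first set fixed and redraws the second set, same size, without
replacement from the networked disease-gene pool; p = (r+1)/(n_perm+1)
with r the count of permuted means ≤ observed.  The plus-one convention
means an observed value beating all 2000 draws reports p = 1/2001 ≈ 0.0005,
never 0.  Distances from the fixed set are pre-computed once (one BFS per
source gene), so each permutation costs only an array lookup; calibration
tests run 500 × 200 permutations in seconds.

**Phenotype similarity** is the mean pairwise cosine of the member
phenotypes' nonnegative feature vectors; a zero-norm row is an error naming
the phenotype.  The permutation draws equally many phenotypes from the
whole matrix; r counts permuted means ≥ observed (ties included, which is
conservative and makes the degenerate "members = all rows" case return
exactly 1).

**Tripartite projection.**  Two herbs are linked when they share at least
`min_shared` responsive genes (default 1; the threshold is exposed because
the right minimum overlap is corpus-dependent), edge weight = shared count;
diseases likewise.  Core genes belong to ≥ 1 herb set and ≥ 1 disease set;
`networked_core` maps them onto the interaction network, optionally
expanded by direct neighbours (`neighborhood=1`) for users who read the
biomolecular module more broadly.  An empty core is flagged, not an error.

## Synergy scoring

The highest-single-agent reference predicts the combination response at
dose pair (i, j) as max(singleA(i), singleB(j)); the excess matrix is the
combination response minus this reference.  Calls use a dead-band of ±5
percentage points by default (configurable): responses from cell assays
carry a few points of noise, and a literal zero threshold would call every
cell synergistic or antagonistic.  Dose "matching" is exact grid alignment
— the factorial design guarantees it — with no interpolation.  Percent
growth and percent inhibition are handled identically.

## Synthetic data generator

The corpus generator emulates the structure the pair score is meant to
detect: planted herb pairs included per formula with probability `co_prob`
and placed adjacently with probability `adjacency_prob`; guide herbs
included Bernoulli(marginal_freq) at a position uniform among the formula's
units; remaining slots filled with distinct random filler herbs; formula
size uniform on `size_range`.  If the included planted/guide herbs
outnumber the drawn size, the size is expanded to fit so inclusion
probabilities stay exact.  The reference conditions
(`default_corpus_spec`) are 60 herbs, 500 formulae of 4–10 herbs, five
planted pairs at co-occurrence 0.3 / adjacency 0.9, and one guide herb at
40% marginal frequency — mirroring a real corpus in which the most frequent
herbs appear in 38–50% of formulae yet their pairings carry little
information.  What the generator does **not** emulate: real herb-frequency
heavy tails, correlated formula families (near-duplicate prescriptions),
dosage, or any pharmacology; passing the recovery benchmark shows the score
separates planted dependence from frequency, not that it reproduces any
particular historical corpus.

The omics generator produces an Erdős–Rényi (default, p = 0.04 on 150
genes) or preferential-attachment interaction network, herb gene sets drawn
from a shared pool (so herbs overlap), disease sets with a tunable fraction
drawn from the herb-gene union (`herb_disease_overlap`, 0 → empty core),
random pathways with one deliberately biased toward the herb genes, and a
phenotype matrix with one planted similar block (`block_similarity`, 1.0 →
identical rows).  Sizes are deliberately small — all statistics here are
exact or permutation-based, so fidelity does not improve with scale, and
the full pipeline runs end-to-end in a few seconds.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; model-level fits derive child seeds for their permutation tests,
  so one seed reproduces every p-value.
- Permutation p-values use the plus-one convention on both tails' counting
  rule (≤ for closeness, ≥ for similarity) with ties counted, which is
  conservative and keeps p in (0, 1].
- Degenerate inputs fail loudly with the offending record named (empty
  formula, duplicate herb, cyclic synonym map, zero-norm phenotype,
  unknown hub herb) except where a defined fallback exists (χ² zero
  margin → p = 1 + flag; empty core → flag).
- Test problem sizes (corpora of ≤ 500 formulae, graphs of ≤ 150 nodes,
  200-permutation calibration) were chosen as the smallest scales at which
  the planted effects are unambiguous; the benchmarks in the acceptance
  tests state their settings explicitly.

## Known limitations

- The pair score is defined for pairs only; triples and larger subsets
  would need a multivariate distance and information measure.
- Formulae are treated as independent samples; near-duplicate formula
  families in real corpora inflate co-occurrence counts and are not
  modelled or corrected.
- The closeness statistic excludes disconnected pairs, so comparing values
  across networks with very different coverage requires care (coverage is
  reported for this reason).
- The phenotype matrix is consumed as-is; constructing meaningful feature
  vectors for phenotypes is out of scope.
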