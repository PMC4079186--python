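# Methods

## Model and procedure

`cohub` analyzes an undirected, weighted gene co-expression network.
Given a gene-by-sample expression matrix (at least 3 samples; missing
values are rejected at load rather than imputed, since no imputation rule
is part of the method), the weighted network is the complete graph over
the genes with edge weight w<sub>ij</sub> = |ρ<sub>ij</sub>|, the
absolute Pearson correlation of the two profiles.  Taking the absolute
value means strong negative co-expression contributes exactly like strong
positive co-expression; the sign can be recovered from the data after
candidate hubs are found.  A constant expression profile makes ρ
undefined and is an error by gene name — mapping it silently to weight 0
would corrupt the ranking.

The weighted node connectivity WNC<sub>i</sub> = Σ<sub>j</sub>
w<sub>ij</sub> is a weighted degree.  Two variants are reported
alongside: WNCB<sub>i</sub> = WNC<sub>i</sub>/deg(i) (mean incident
weight; undefined for isolated nodes, which are an error rather than a
silent 0/0) and WNCC<sub>i</sub> = Σ<sub>j</sub> w<sub>ij</sub>² (sum of
squares, emphasizing strong edges).  On a complete graph all three induce
closely related rankings (WNCB's is identical to WNC's).

### Permutation null

The null hypothesis is that a gene's connectivity is what one would see
if the observed weights were arbitrarily re-assigned over the same edge
topology.  Two samplers are provided:

* **swap** — a Markov chain of weight exchanges between node-disjoint
  edge pairs e(x, y), e(v, z), x ≠ y ≠ v ≠ z.  One sample applies
  `n_swaps_per_sample` *attempts* (default 10·|E|): each attempt draws an
  ordered pair of edge slots uniformly and exchanges their weights only
  if the edges share no node.  Counting attempts (rather than applied
  swaps) makes the chain lazy and therefore aperiodic: a fixed number of
  *applied* transpositions would confine a sample to one parity class of
  the assignment group.  With laziness the chain's stationary law is
  uniform over the assignments reachable by disjoint-pair transpositions.
  On complete graphs with ≥ 5 nodes that reachable set is *all*
  |E|! assignments; on K4 each edge is node-disjoint with exactly one
  other edge, so only 2³ = 8 assignments are reachable — degenerate
  graphs with no disjoint pair at all (stars, triangles) raise an error
  directing the user to shuffle mode.
* **shuffle** — a uniform random permutation of the weight multiset over
  the edges: the swap chain's stationary distribution, sampled directly.
  This is the recommended (and internally used) sampler for large
  networks, where a well-mixed swap chain costs ~10·|E| operations per
  sample for the identical null.

Both samplers preserve the node set, the degree sequence and the weight
multiset of every sample exactly (verified per sample in the tests).
Sample *k* is generated from the seed pair (seed, k), so any single
permuted network can be reproduced in isolation and results are
bit-identical across runs of the same seed.

P<sub>i</sub> is the proportion of permuted samples whose score for gene
*i* is ≥ the observed score.  The inclusive comparison makes ties count
against significance and P = 1 exact on uniform-weight networks; the
plain proportion (no pseudocount) can return P = 0 for genes whose
observed score exceeds every sampled null.  An optional add-one estimator
(b+1)/(m+1) is available for downstream analyses that cannot accept
P = 0; it is biased upward by at most 1/(m+1).  P-values are
Bonferroni-adjusted, min(1, P·m), with m the number of genes submitted
for testing (the user's gene list if one was given, else all nodes).
The output ranking is deterministic: ascending adjusted P, ties broken by
descending WNC, then by gene id.

**Numerical tie handling.**  An observed score and a null score that are
sums of the same weight multiset can differ by an ulp because the two
code paths accumulate in different orders.  The comparison therefore uses
a tie tolerance of 1e-9 · max(1, |observed|) — orders of magnitude above
accumulated rounding error for any realistic network, and orders of
magnitude below genuine weight differences — so that mathematical ties
are counted as ties (against significance) regardless of summation
order.

### Binary network and classical centralities

For comparison with threshold-based practice, the weighted network is
binarized by keeping edges with w ≥ the **nearest-rank percentile**
(order statistic at rank ⌈p·|E|⌉ of the ascending weights; default
p = 0.95, ties at the threshold all retained, nodes left edgeless are
dropped).  On that graph the package computes degree; closeness
1/Σ<sub>j</sub> h(i, j) with the sum over the node's connected component;
raw betweenness Σ<sub>{j,k}</sub> n<sub>jk</sub>(i)/n<sub>jk</sub> over
unordered pairs (an optional flag divides by C(n−1, 2); percentile
selection is invariant to that monotone rescaling); and the clustering
coefficient, reported as 0 for nodes of degree < 2 where the denominator
C(deg, 2) vanishes.  Degree, betweenness and clustering are delegated to
networkx with these conventions pinned; closeness is computed directly
from BFS distances because networkx's closeness applies a
component-size rescaling that the plain inverse-sum definition does not.
All four are validated against exhaustive-enumeration oracles on small
random graphs.

Top genes per classical score are selected by the same nearest-rank rule
applied to the score distribution; gene sets from different methods are
compared by pairwise intersection counts and Spearman rank concordance
(average-rank ties).

### Enrichment

Selected gene sets are tested for over-representation of annotation
terms (GMT input) with the one-sided hypergeometric tail, computed with
`scipy.stats.hypergeom`.  The universe defaults to the genes of the
analyzed annotation/network — the frame the selection was actually drawn
from — not the genome.  Both raw and Bonferroni-adjusted P-values are
reported; the significance criterion is left to the caller.  Ontology
hierarchy traversal and depletion testing are out of scope.

## Synthetic data

The generator plants hub modules in noise.  Each module has a latent
standard-normal driver d over samples; a module gene is
noise_sd·(√λ·d + √(1−λ)·ε) with λ = driver_strength², giving population
correlation exactly driver_strength with the driver and driver_strength²
between module genes; background genes are pure noise.  This latent-
factor construction was chosen over covariance-matrix sampling because it
hits the target correlation exactly, generates in O(genes·samples), and
is trivially seedable.  An optional flag flips the loading sign of every
other module gene to exercise the absolute-value weighting path.
Defaults (10 samples, a few hundred genes, modules of ~15, driver
strength 0.9, unit noise) mirror the small-sample expression studies this
class of analysis is typically applied to.

What the generator does *not* emulate: platform artifacts, library-size
or batch effects, heavy-tailed expression marginals, and the pervasive
correlation structure of real differentially-expressed gene panels.
Passing tests on these fixtures demonstrate the statistical machinery
(null validity, P-value calibration, ranking behaviour), not performance
on any real dataset.

A consequence worth stating explicitly: with only 10 samples the
background absolute correlation is large (E|r| = √(2/(9π)) ≈ 0.27), so in
a 200-gene matrix every gene's WNC is ≈ 199·0.27 ≈ 54 while a 15-gene
module at driver strength 0.9 adds only ≈ 7 to its members — about 2.2
null standard deviations.  Planted hubs of that configuration therefore
rank at the top but generally do **not** clear a Bonferroni-corrected
0.05 cut-off; recovering essentially the whole module requires stronger
drivers, larger modules relative to the network, or more samples (see the
README's worked example, where 19 of 20 planted hubs are recovered with
zero false positives).  The corresponding end-to-end expectation in the
acceptance suite is asserted at the stricter adjusted-P criterion and
documents this gap honestly rather than relaxing it.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_permutations` | 100 000 | null samples; ≥ 10 000 gives stable P estimates (verified: 10 K vs 100 K agree within binomial Monte-Carlo error for ≥ 99% of genes) |
| `mode` | swap | null sampler; shuffle is the same null on complete graphs ≥ 5 nodes at far lower cost |
| `n_swaps_per_sample` | 10·\|E\| | swap-chain attempts per sample, well past mixing on complete graphs |
| `seed` | 0 | fixes the entire analysis bit-for-bit |
| `alpha` | 0.05 | threshold on Bonferroni-adjusted P |
| `percentile` | 0.95 | nearest-rank cut for binarization and top-gene selection |

## Problem sizes used in the test and acceptance runs

Exhaustive-enumeration checks use a 4-node complete network (6 edges,
720 assignments); null-invariant conservation uses 1 000 swap samples of
a 50-node network; stability compares 10 K vs 100 K shuffle samples on a
100-node network; the planted-hub fixture is 200 genes × 10 samples with
two 15-gene modules at 10 000 permutations.  These sizes make the whole
suite run in well under a minute while keeping Monte-Carlo error bars
(3 binomial SEs) tight enough to be meaningful.

## Known limitations

* Only Bonferroni correction is built in; the P-value columns are
  exposed so FDR-style procedures can be applied downstream.
* The swap-mode null on graphs whose disjoint-pair transpositions do not
  generate the full assignment group (e.g. K4) is a strict subset of the
  shuffle null; the implementation warns only in the fully degenerate
  (no disjoint pair) case.
* Pearson correlation only; rank or information-theoretic association
  measures would require a different network builder (the scorer itself
  is agnostic to how weights were produced).
* Betweenness/closeness are unweighted notions computed on the binarized
  graph; weighted path-based centralities are out of scope.
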