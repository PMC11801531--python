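# Methods

## Model and assumptions

The predictor rests on one biological assumption: drugs acting on
identical or closely related pathways are more likely to combine
synergistically. "Closeness" is measured on a pathway relationship
network derived purely from gene-set overlap, so the method needs no
training data — the only inputs are pathway gene sets, drug→target and
target→pathway annotations, and a labelled pair list for evaluation.

### Overlap test

For pathways $P_i, P_j$ the 2×2 table $(a,b,c,d)$ counts genes in both,
only the first, only the second, and neither, with the population $M$
fixed to the union of *all* pathway gene sets in the universe (not the
whole genome — genes never annotated to any pathway carry no information
about pathway relatedness here). Two p-value conventions are exposed:

* `point` — the hypergeometric mass of the observed table itself,
  $\frac{(a+b)!(c+d)!(a+c)!(b+d)!}{a!\,b!\,c!\,d!\,M!}$;
* `greater` (default) — the one-sided over-enrichment tail, the sum of
  point masses over all tables with the same margins and intersection
  $\ge a$. This is what "Fisher's exact test" conventionally means when
  testing for *excess* overlap, which is what edge-building rewards.

Both are computed with log-gamma arithmetic and clipped to $[0,1]$; a tail
sum within $10^{-12}$ of 1 is snapped to exactly 1 so the strict
$p < \text{threshold}$ rule behaves correctly at a threshold of 1. No
multiple-testing correction is applied across the $\binom{n}{2}$ pairs:
the threshold $p$ is an explicit tuning parameter, not an error rate.

Degenerate cases worth knowing: $a=0$ gives a `greater` p-value of exactly
1 (never an edge under the strict inequality), and a table whose margins
admit only one configuration (e.g. $b=c=0$ with $a=0$ or $d=0$) has point
probability 1.

### Network and distances

Edges join pathway pairs with $p_{ij}$ strictly below the threshold
(default 0.001) and carry unit length; p-values never weight edges. All
pathways remain nodes even when isolated, so same-pathway scoring still
applies to them. Distances are computed by the Floyd–Warshall recurrence
(vectorised over rows per intermediate vertex $k$ — algebraically
identical to the triple loop); unreachable pairs are $+\infty$. The full
p-value matrix is cached on the network object so threshold sweeps re-cut
the graph without re-testing.

### Pair score

The score aggregates over the *ordered* product $P_A \times P_B$: a
pathway shared by both drugs contributes $C$ once per ordered occurrence,
and its finite cross-distances to the other drug's pathways also count.
Identity is decided by pathway ID equality, not by a zero matrix entry.
Unreachable pathway pairs contribute 0, which means a fully disconnected
pair scores $e^0 = 1$ — higher than a connected pair at mean distance 1.
This is a deliberate property of the aggregation rule as defined, and one
reason scores must be treated as ranks only. With $C<0$ the score can be
astronomically large ($e^{100}$ for two single-pathway drugs sharing their
pathway at $C=-100$); AUC, being rank-based, is invariant to this scale.

### Parameters

| parameter | default | meaning |
|---|---|---|
| $C$ | −100 | same-pathway distance (dimensionless); negative values up-weight shared pathways. AUC is monotone non-increasing in $C$ whenever only positives share pathways, and plateaus once $C$ dominates the finite distances |
| $p$ | 0.001 | strict edge threshold on the overlap p-value |
| sidedness | greater | which p-value convention builds the network |
| negative ratio | 5 | negatives per positive in evaluation (curated ineffective pairs fill the quota first, then a seeded uniform sample without replacement) |

### Evaluation

The ROC sweep takes every distinct sample score as a threshold, calling a
sample positive only when its score *strictly exceeds* the threshold
(ties are called negative), with $\pm\infty$ sentinels supplying the
$(0,0)$ and $(1,1)$ endpoints; AUC is the trapezoidal area. Reported AUCs
use the Mann–Whitney rank estimator (ties credited 0.5), which equals the
trapezoid under this tie-grouping convention to floating-point precision —
the test suite asserts agreement to $10^{-10}$ including heavily tied
score sets.

## Synthetic benchmark

The generator emulates a curated drug-combination corpus at the scale of
the angina use case: 94 drugs, 94 planted positive pairs, 12 curated
ineffective pairs, a 1:5 positive:negative ratio and 330 pathways.
Structure:

* Pathways fall into 20 contiguous clusters; cluster members share a core
  gene block (half of each 40-gene pathway, from a 5000-gene universe),
  making every within-cluster pair significant at $p \ll 0.001$ — each
  cluster is a clique at distance 1.
* Consecutive clusters are chained by a bridge gene block shared between
  the last pathway of one cluster and the first of the next, so the
  network is connected and between-cluster distances grow with cluster
  separation (roughly two hops per cluster).
* Each target maps to exactly one pathway (two targets per pathway);
  drugs draw their targets from their home cluster and their pathway sets
  are derived through the target map — the same code path real data uses.
* Positive pairs are planted within a cluster: under `same_pathway` both
  drugs receive a target on one common pathway (the C term fires); under
  `adjacent_pathway` the two drugs draw from disjoint halves of the
  cluster's pathways, so they share no pathway ID but sit at distance 1
  (only the distance term fires).
* Negatives are sampled among drug pairs whose home clusters are at least
  two apart, i.e. pairs with distant pathway sets. The target interaction
  network is the per-pathway target cliques plus a chain, mirroring the
  pathway topology.

Cluster count, gene universe size, pathway size and the shared-gene
fraction are the package's own choices of a realistic regime (strong
within-cluster overlap, negligible chance overlap: a random pathway pair
shares ~0.4 genes in expectation, far from the ~7 needed for
significance). All randomness flows from a single integer seed through
one generator, and files are written in sorted order, so outputs are
byte-identical across runs.

**What passing tests show — and what they do not.** The planted benchmark
is cleanly separable by construction: positives either share pathways or
sit at distance 1 while negatives are several hops away, so the flagship
method attains AUC ≈ 1 and the C-sweep plateaus immediately. This
validates the machinery (network construction, distances, aggregation,
ranking), not real-world effect sizes: curated corpora have noisy,
overlapping annotations, negatives that are merely unlabelled, and
pathway networks whose distances compress after thresholding, all of
which push AUC well below 1. The adjacent-pathway mechanism is the
discriminating case: there the pathway-overlap baseline is blind (AUC
0.5) while the distance term still separates, which is precisely the
claimed value of using the network rather than set overlap alone.

## Numerical and design choices

* Factorials via `scipy.special.gammaln`; exact-rational brute force is
  used as the test oracle up to margin 12.
* The Floyd–Warshall recurrence is the distance implementation; a
  per-source BFS serves as an independent oracle in tests (on unit-length
  graphs the two must agree exactly).
* Score ties in output files break lexicographically on (drug_a, drug_b)
  for deterministic artifacts.
* Drugs with empty pathway sets survive I/O but any attempt to score them
  fails up front, listing every offending drug.
* Negative sampling is without replacement over unordered pairs and
  refuses infeasible quotas, reporting the maximum achievable ratio.
* The `path_dis`/`tar_dis` baselines reuse the flagship aggregation with a
  same-node distance of 0, so comparisons against the flagship isolate
  exactly the contribution of the C term / the node universe.

## Limitations

* Pairs only; no three-drug combinations.
* Scores are uncalibrated ranks; do not interpret them as probabilities.
* Identifiers are opaque strings assumed pre-harmonised across sources;
  no ontology mapping is attempted.
* The pathway-interaction comparison method that scores same-pathway
  pairs through a protein-interaction network (rather than a constant C)
  is not implemented; the `tar_dis` baseline covers the
  target-network-only viewpoint instead.
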