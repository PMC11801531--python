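# hprna

Network-based prediction of synergistic drug combinations from pathway
gene-set overlap.

Synergistic drug pairs — combinations whose joint effect exceeds the sum of
the single-drug effects — tend to act on identical or closely related
biological pathways. This package ranks candidate drug pairs by exploiting
exactly that signal. It is aimed at computational pharmacologists who have,
for a disease area of interest, (a) pathway gene sets (e.g. KEGG-style GMT
files), (b) drug→target and target→pathway annotation tables, and (c) a
small labelled list of known effective / ineffective combinations to
evaluate against.

## The method

1. **Pathway relationship network.** For every pair of pathways
   $P_i, P_j$ with gene sets $G_i, G_j$, form the 2×2 contingency table
   $a=|G_i\cap G_j|$, $b=|G_i\setminus G_j|$, $c=|G_j\setminus G_i|$,
   $d=M-|G_i\cup G_j|$, where $M$ is the number of genes in the union of
   all gene sets. Fisher's exact test on this table gives a p-value
   $p_{ij}$; pathways with $p_{ij} < p$ (default $p=0.001$) are joined by
   an edge of unit length. Both the one-sided over-enrichment tail and the
   literal single-table hypergeometric mass
   $\frac{(a+b)!\,(c+d)!\,(a+c)!\,(b+d)!}{a!\,b!\,c!\,d!\,M!}$
   are available as the p-value ("greater" is the default).
2. **Distances.** All-pairs shortest-path lengths $SPL(P_i,P_j,G)$ on the
   thresholded graph, via the Floyd–Warshall recurrence
   $D_{ij} \leftarrow \min(D_{ij}, D_{ik}+D_{kj})$.
3. **Pair score.** For drugs $A, B$ with pathway sets $P_A, P_B$:

   $$\mathrm{SCORE}(A,B) = \exp\!\Big(-\frac{\sum_{(i,j)\in P_A\times P_B} d(P_{Ai},P_{Bj})}{|P_A|\,|P_B|}\Big),$$

   where $d = C$ when the two pathways are identical (default $C=-100$, so
   shared pathways strongly raise the score), $d = SPL$ when they are
   connected, and unreachable pairs contribute nothing. Scores are ranks,
   not probabilities — with $C<0$ they may exceed 1.
4. **Evaluation.** Threshold-sweep ROC (a sample is called positive when
   its score strictly exceeds the threshold) and AUC, equal to the
   Mann–Whitney probability that a random positive outscores a random
   negative. Negatives are curated ineffective pairs topped up with a
   seeded uniform sample of unlabelled pairs at a 1:5 positive:negative
   ratio.

Four baselines are included for comparison: cosine similarity of target
sets (`tar_overlap`) or pathway sets (`path_overlap`), and the same
exponential distance aggregation on a protein-interaction network over
targets (`tar_dis`) or on the pathway network with a same-node distance of
0 instead of C (`path_dis`).

Real annotation databases are deliberately not bundled; a synthetic
benchmark generator emulates the whole data model (gene universe, pathway
clusters with controlled overlap, target-derived drug pathway sets, planted
synergistic pairs, distant negatives) so the pipeline is testable
end-to-end from a single seed.

## Worked example

Simulate a small benchmark, build the network, score and evaluate:

```sh
hprna simulate --seed 7 --n-genes 800 --n-pathways 12 --genes-per-pathway 20 \
    --n-clusters 4 --n-drugs 20 --targets-per-drug 2 --n-planted 10 \
    --negative-ratio 5 --n-ineffective 2 --out data
hprna build-network --gene-sets data/pathways.gmt --out net
hprna score --distances net/distances.tsv --drug-targets data/drug_targets.tsv \
    --drug-pathways data/drug_pathways.tsv --pairs data/labels.tsv \
    --methods hprna,path_overlap --out scores.tsv
hprna evaluate --scores scores.tsv --labels data/labels.tsv --seed 7 --out eval
```

This prints, among other log lines:

```
INFO network: 12 pathways, 15 related pairs (p<0.001, greater)
INFO wrote 120 scores (60 pairs x 2 methods) to scores.tsv
INFO method hprna: AUC=1.0000 (10 pos, 50 neg)
INFO method path_overlap: AUC=1.0000 (10 pos, 50 neg)
```

The 12 pathways form 4 overlap clusters chained together (15 significant
pairs); the 10 planted synergistic pairs share pathways, so with $C=-100$
they receive enormous scores (`head scores.tsv` shows values like
`3.14e+21`) while the 50 distant negatives score below 1, giving AUC 1.0 —
the planted signal is fully recovered. `eval/summary.json` records the AUC,
pair counts and seed per method; `eval/roc_<method>.tsv` holds the ROC
points. `hprna sweep` evaluates a grid of $C$ and $p$ settings in one run.

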