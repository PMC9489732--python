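# Methods

## Model

Long-read proximity ligation (Pore-C) reports, per sequencing read, a set of
aligned fragments ("monomers") that were cross-linked together — a direct
observation of a multi-way chromatin contact. We represent a sample as a
genomic hypergraph G = {V, E}: nodes are genomic loci (bins of a chosen
resolution, or individual monomer intervals at read level) and each
hyperedge is one multi-way contact. The n x m incidence matrix **H** has a
row per locus and a column per contact; a column sum is the contact's order,
a row sum the locus degree.

### Binning

A monomer is assigned to the bin containing its fragment midpoint. The
midpoint rule avoids double-assigning fragments that straddle a bin
boundary, and makes re-binning exactly nested: binning at resolution r and
then coarsening to a multiple of r equals binning directly at the coarser
resolution (floor division composes). Duplicate bins within one read
collapse, so a read's hyperedge order can shrink; reads collapsing to a
single bin are kept as order-1 self-contacts (they contribute to incidence
matrices and to the contact-matrix diagonal but never to pairwise filtering
statistics). Identical hyperedges merge with a multiplicity weight. By
default hypergraphs are treated as weighted at coarse resolutions
(>= 1 Mb), where recurrent contacts accumulate, and unweighted at read
level / fine bins, where almost all contacts are unique; both are
overridable. When a chromosome-sizes table is supplied, the node universe is
all bins of the listed chromosomes in table order, so hypergraphs from
different samples share a row order and can be compared directly.

### Filtering

Multi-way contacts are decomposed into their pairwise locus combinations and
each distinct pair's weighted recurrence is counted. The support threshold
is the nearest-rank 85th percentile (configurable) of the per-pair count
distribution; a pair is supported iff its count reaches the threshold.
Within each hyperedge the node incident to the most unsupported internal
pairs is removed, ties broken toward the lower node index, until all
remaining internal pairs are supported; hyperedges reduced below two nodes
are dropped and identical survivors re-merge. Because trimming lowers the
counts of surviving pairs, a single pass is not idempotent: re-running it
would see a different count distribution and threshold. The filter therefore
iterates the pass to a fixpoint, which makes it idempotent by construction
and leaves all single-pass-stable inputs (including the small worked
examples) unchanged. The node-trimming rule itself is one of several
defensible readings of "remove unsupported pairs" (alternatives: drop the
whole hyperedge, or only exclude the pair from downstream pairwise
statistics); it is the least destructive option that still guarantees every
surviving internal pair is supported.

### Entropy

With **D** = diag(node degrees) and **E** = diag(hyperedge orders), the
hypergraph Laplacian is

    L = D - H E^-1 H^T.

L is symmetric positive semidefinite with zero row sums: row i of
H E^-1 H^T sums to the degree of node i because each hyperedge containing i
spreads a total mass of 1 over its members. Hypergraph entropy is the
Shannon entropy of the trace-normalized spectrum,
S = -sum_i lam_bar_i ln lam_bar_i with lam_bar_i = lam_i / sum(lam) and
0 ln 0 = 0 — the von Neumann entropy of L / tr(L). Closed forms used as
oracles: a single pairwise hyperedge has spectrum {0, 1} and entropy 0; a
single hyperedge covering all n nodes gives L = (I - J/n) with spectrum
{0, 1 x (n-1)} and entropy ln(n-1).

The often-reproduced worked example with hyperedges {v1,v2,v3} and {v3,v4}
has a printed diagonal entry 5/3 at position (3,3) in some derivations; the
defining equation gives 7/6 (degree 2 minus 1/3 + 1/2), and only 7/6 makes
row 3 sum to zero, as any Laplacian row must. We implement the equation and
treat 7/6 as correct; the remaining entries (2/3, -1/3, -1/2, 1/2) and the
clique-expansion graph Laplacian agree with the usual presentation and are
locked in by tests.

### Distances

Samples sharing a node universe are compared through per-sample matrices
A = H E^-1 H^T (adjacency with diagonal),
L~ = I - D^-1/2 A D^-1/2 (normalized Laplacian; rows and columns of
zero-degree loci are zeroed rather than dropped so all samples keep the same
n), and the fast-belief-propagation affinity S = (I + eps^2 D^a - eps A)^-1
with D^a = diag(row sums of A):

* Hamming: (1/n^2) sum |A1 - A2| — local.
* Spectral: (1/n) p-norm of the difference of the ascending eigenvalues of
  the two normalized Laplacians (p = 2 by default) — global, invariant to
  node relabeling.
* DeltaCon: (1/n^2) Matusita difference of sqrt(S1) and sqrt(S2) — mixes
  local and global structure; eps defaults to 1e-3.

A scaling caveat for DeltaCon: for small eps the off-diagonal affinities are
approximately eps * A_jk, so the Matusita terms scale as sqrt(eps) and the
raw distance grows roughly as sqrt(eps) — about 3.2x per decade of eps.
Relative comparisons between sample pairs, rankings, and permutation
p-values are invariant under this common scaling (which is what makes the
measure usable across eps choices), but the absolute distance is not
eps-stable and should only be compared across runs that fixed eps.

### Permutation significance of distances

The null model generates hypergraphs "similar" to G1: every hyperedge keeps
its order and weight while its members are redrawn without replacement with
probability proportional to G1's weighted node degrees (a bipartite
configuration-style null that matches expected degrees; exact
degree-sequence preservation via edge swaps was rejected as slower and not
better determined). The p-value alpha is the proportion of N background
distances d(G1, R_i) that are >= the observed d(G1, G2); the >= convention
means ties count toward the null, making alpha conservative, and alpha = 0
means no background draw reached the observed distance. N defaults to 1000.

When the distance statistic is discrete (small hypergraphs with
pairwise-only contacts produce distances on a coarse lattice), ties are
common and alpha is noticeably conservative; the calibration tests exploit
this regime deliberately, because with a continuous statistic the event
"alpha >= 0.05" has probability 191/201 under the null at N = 200 — exactly
at the nominal level, so any finite calibration check would sit on a
sampling boundary.

## Transcription clusters

Cluster calling works on read-level contacts. Each locus, extended +/- 5 kb
(clipped to the chromosome), is intersected with accessibility peaks
(ATAC/DNase), RNA Pol II ChIP-seq peaks, and gene bodies; gene expression is
attached from an RNA-seq table, with "expressed" meaning expression >= 1 on
a TPM-like scale by default (the threshold is configurable; any positive
cutoff behaves identically on the synthetic data, where planted genes are
expressed at ~50 and background genes at 0).

Tiers, each contained in the previous:

1. **Potential**: every locus accessible and >= 1 locus Pol II-bound
   (order >= 2 after collapsing).
2. **Cluster**: >= 2 expressed genes sharing a transcription factor. A TF
   "binds" a gene when the motif-scanner count within +/- 5 kb of the TSS is
   >= 3 sites (configurable); with exactly two expressed genes a common TF
   must bind both, with three or more it must bind a strict majority.
3. **Specialized**: >= 1 common TF is a master regulator (MR) — a TF whose
   motif occurs (>= 3 sites) at its own encoding gene, per the TF-to-gene
   sidecar map.
4. **Self-sustaining**: the cluster contains an expressed TF-encoding gene
   whose TF also binds >= 1 gene in the same cluster ("at the cluster" is
   read as binding a cluster gene through the motif table; binding within
   the flanked loci directly would be the stricter alternative). **Core**:
   additionally that TF is an MR — core clusters are therefore also
   specialized.
   TFs whose encoding gene is expressed in one cluster while the TF binds
   only in others form the analog-independent class; TFs binding a cluster
   whose gene is expressed in no cluster are tallied genome-wide.

Enrichment of architectural factors (CTCF, RAD21, SMC3, enhancers) at
clusters is the fraction of clusters with >= 1 flanked locus overlapping a
peak, compared with order-matched random contact samples over N trials
(one-sided, >= tail). Criteria significance partitions contacts by order
(3, 4, 5, 6+), draws per trial as many random contacts as there are
candidates of that order, counts how many satisfy each criterion (>= 1
expressed gene, >= 2, common TFs, common MRs), and reports the proportion of
trials meeting or exceeding the observed count, plus a pooled "all" row.

## Synthetic data

The generator emulates the six input types with planted structure. Default
study conditions: a 4-chromosome, 57 Mb toy genome; 2,000 reads with
background contact orders 2..6 at probabilities (0.45, 0.25, 0.15, 0.10,
0.05) — monotonically decreasing, the qualitative shape of observed Pore-C
order distributions; 30% inter-chromosomal mixing; 20 planted clusters
(4 per tier) of orders 3..6, two reads each; planted loci of ~1 kb with
accessibility peaks at every locus, one Pol II peak, expressed genes within
the flank, and per-cluster TFs wired so each tier's defining condition holds
by construction (self-sustaining-but-not-core clusters get three genes so
the shared TF can bind a strict majority without binding its own encoding
gene). Planted loci occupy a reserved stripe (first 25% of each chromosome)
and background monomers are drawn outside it with a flank-sized margin, so
at zero background noise the planted tiers are recoverable exactly —
structural separation, not a tuned margin. Background noise rates (peak,
gene and sub-threshold motif densities, expression noise) re-introduce
annotation outside the stripe; they default to zero and are the knobs for
robustness experiments.

What the generator does not emulate: polymer-physics contact decay with
genomic distance, restriction-fragment structure, mappability artifacts,
cell-type mixtures, or realistic motif count distributions. Passing the
recovery tests therefore shows the pipeline implements its definitions
exactly, not that the definitions are robust on real data.

Perturbations for distance calibration: "relocate" moves a fraction of
hyperedges to a disjoint node block (index shift by n/2 mod n; at strength 1
on a half-occupied universe the supports are disjoint and the Hamming
distance equals the summed adjacency masses over n^2 — note full relocation
is a relabeling, so the spectral distance returns to zero there); "rewire"
replaces node memberships uniformly at random with the given probability.

## Numerical choices

* Symmetric eigensolvers throughout; eigenvalues of L clipped at 0 (PSD up
  to round-off, tolerance 1e-9) and sorted ascending before use.
* Matrices symmetrized as (M + M^T)/2 after products to suppress round-off
  asymmetry.
* eps for DeltaCon restricted to (0, 1); negative affinity entries (possible
  at large eps) raise an error advising a smaller eps rather than silently
  clipping structure.
* Nearest-rank percentile: smallest value with at least p% of the
  distribution at or below it.
* Tie-breaks are deterministic everywhere (lower node index in filtering,
  lexicographic hyperedge order in rankings, TF name in TF rankings), so
  equal inputs and seeds give byte-identical outputs.
* Weighted hypergraphs enter spectral computations as repeated incidence
  columns (weight w -> w identical columns), which keeps the counting
  semantics of D and E and the handshake identity.

## Problem sizes

Tests and the acceptance script run on desk-scale instances chosen to keep
the whole suite fast while leaving every code path exercised: 4-10 node
worked examples and toys, 100 random toy pairs for distance axioms, 50
calibration repeats at 200 permutation trials, a 5,000-read simulation for
planted recovery with 200-trial criteria tests, and 1,000-trial enrichment.
Genome-scale runs only change n and m, not the code paths.

## Known limitations

* Hypergraph entropy is not normalized for hypergraph size, so entropies of
  differently-sized chromosomes are not directly comparable.
* The similar-hypergraph null matches degrees in expectation only.
* Raw DeltaCon values depend on eps as sqrt(eps) (see above).
* The filter's node-trimming rule and the expression threshold are
  field-reasonable choices, exposed as parameters, not derived quantities.
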