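# Methods

## Data model

The unit of observation is a participant's response: an ordered list of
identity labels (1–10, the survey cap) and, per identity, a list of
behaviour labels. Labels are assumed pre-coded: ingestion only
whitespace-normalizes and case-folds them, and duplicate
(participant, identity, behaviour) rows collapse to one. The qualitative
re-coding of free text into labels is upstream of this package.

Each network kind maps responses to a binary samples-by-items occurrence
matrix:

| kind | sample (row) | item (column/node) |
|---|---|---|
| identity_by_identity | participant | identity |
| behaviour_by_identity | (participant, identity) entry with ≥1 behaviour | behaviour |
| identity_by_behaviour | behaviour label (population-aggregated) | identity |

The identity-by-behaviour construction aggregates each behaviour into one
row — its edge weights count *behaviour labels* shared between identities,
not individual mentions. A per-mention variant would weight common
behaviours more heavily; the aggregated form is the default because the
permutation null for this network swaps identity labels between behaviour
samples.

**Node filter.** Retained nodes are those whose column total exceeds the
threshold (default 3, i.e. observed at least 4 times) *in their own
occurrence matrix*: participants reporting the identity, entries listing
the behaviour, or distinct behaviours linked to the identity, respectively.
Rows left with no retained item are dropped — they cannot inform any
association and would freeze checkerboard swaps.

## Association index

`SRI(A,B) = x / (x + y_a + y_b)` with x = samples containing both items and
y_a, y_b = samples containing exactly one. The classical index also has a
y_ab term (both observed in the same sampling period but apart); a sample
here is a single response list, so y_ab is structurally zero. Pairs whose
denominator is zero (neither item in any retained sample — impossible for
identity-by-identity, possible for the derived matrices) get weight 0 with
a logged warning: "no information" is treated as "never associated" for
structural metrics.

## Structure metrics

* **Density** `2E/(n(n−1))`, E = dyads with positive weight. Invariant to
  weight rescaling.
* **CV of dyad weights** — sample SD (n−1) over mean. Computed over *all*
  unordered dyads including zeros (default): the permutation null moves
  weight between dyads, so absent edges carry information. A
  nonzero-dyads-only variant is config-exposed and recorded in output
  metadata.
* **Betweenness** — Freeman betweenness over weighted shortest paths with
  fractional credit among ties, unnormalized, via networkx. The default
  `weight_mode="cost"` feeds association weights directly in as path
  lengths. That convention is deliberately the one of the graph libraries
  usually run on association matrices (so scores are comparable with
  published tables), even though semantically a strong association should
  shorten a path; `"similarity_reciprocal"` (length = 1/weight) is the
  semantically clean alternative. The mode used is recorded in the
  metrics JSON.
* **Walktrap** — Pons–Latapy agglomeration with 4-step random walks. The
  walk is lazy (every node carries an implicit self-loop equal to its
  strength, so P_ii = ½), matching the reference implementation's
  convention; community profiles merge as size-weighted means, the merge
  criterion is the Ward-style Δσ, merge ties break on the smallest
  (min, max) node-index pair, and the returned partition is the
  dendrogram level with maximum weighted modularity. Connected components
  agglomerate independently; isolated nodes stay singletons. On
  well-separated planted benchmarks the partitions coincide with
  python-igraph's walktrap; on unstructured graphs the two can differ in
  near-tie merges while scoring essentially equal modularity.
* **Modularity** `Q = Σ_c [w_in(c)/m − (s(c)/2m)²]` with m the total edge
  weight, w_in the within-module weight and s the module strength.

## Permutation null

The null holds fixed (1) the number of samples, (2) items per sample, and
(3) each item's total count. It is sampled by a Markov chain of 2×2
checkerboard swaps. Two details matter for correctness:

1. **Uniformity.** A chain step draws one uniformly random
   (row pair, column pair) proposal and swaps iff it forms a checkerboard;
   rejected proposals count as self-loops. This makes the kernel symmetric
   and the stationary distribution exactly uniform over matrices with the
   observed margins. (Re-drawing until a swap is found instead samples
   neighbors uniformly, which biases the stationary law toward matrices
   with many swappable submatrices.) `swaps_per_permutation` therefore
   counts proposal steps; the default 500 corresponds to roughly 20
   accepted swaps between recorded samples at survey scale.
2. **Serial validity.** Rather than burn-in-then-sample, the default
   `scheme="anchored"` uses the Besag–Clifford serial construction: two
   independent runs leave the observed matrix (U samples and n−U samples,
   U uniform on 0..n; by reversibility the "backward" run is just another
   forward run). Their union is a stationary path with the observed state
   at a uniformly random position, so the rank of the observed statistic
   among the n null values is exactly uniform under the null at *any*
   chain length — the test is calibrated even when mixing is slow. The
   classic forward scheme (`scheme="forward"`, burn-in default 1,000
   proposals) is retained for reproducing the traditional procedure; it
   is only asymptotically valid and anticonservative at small permutation
   counts.

The global statistic is the CV of all dyad weights; `global_p` is the
plus-one proportion `(k+1)/(n+1)` of null values at least as large as the
observed one (the raw proportion k/n is config-exposed). Dyad tests reuse
the same chain: for every unordered node pair, `p_upper` / `p_lower` are
the plus-one proportions of null weights ≥ / ≤ the observed weight, ties
counting toward both tails (conservative); *preferred* means
`p_upper ≤ (1−α)/2`, *avoided* `p_lower ≤ (1−α)/2`, α = .95 by default.
Defaults follow the analysed study: 10,000 permutations, threshold 3,
α = .95, walktrap steps 4.

A matrix admitting no swap (e.g. all-ones) is *frozen*: the report flags
it and the public single-swap operation warns and returns its input.

## Mantel test

Both matrices are restricted to their shared nodes (≥3 required) in a
common order; r is the Pearson correlation of the upper-triangle dyad
vectors; p is two-tailed over simultaneous row/column relabelings of one
matrix, plus-one convention, default 10,000 permutations with an own seed
stream. All shared-node dyads enter, zeros included.

## Synthetic generator

The generator emulates the survey's marginal statistics and, on top of a
structureless baseline, plants known signal:

* **Counts.** Identities per participant and behaviours per identity are
  discretized truncated normals on 1–10, moment-matched to
  (mean 5.20, SD 1.95) and (mean 2.06, SD 1.26) respectively (the data's
  published descriptives); matching is solved once per configuration by
  least squares and fails loudly if the targets are infeasible.
* **Label popularity.** Zipf weights with exponents 1.3 (identities) and
  1.9 (behaviours). Two exponents are needed because behaviour labels are
  drawn roughly twice as often per label; these values reproduce the
  observed heavy-tailed vocabulary shape (of ~138/83 labels, ~60/~38
  survive the >3 filter at n = 286).
* **Structureless baseline = conditional Poisson sampling.** Given a list
  length k, the identity set is drawn with probability proportional to the
  product of its label weights (sequential ESP-table sampling). This is
  the one scheme for which the whole matrix is *conditionally uniform
  given its margins* — the property the permutation null tests — so null
  datasets are calibrated by construction. Sequential weighted draws
  without replacement do **not** have this property (popular labels
  co-occur excessively; measured rejection rates of 80%+ at nominal 5%).
  Behaviour draws use the same scheme.
* **Planted blocks.** A participant holding any member of a block pulls in
  each missing block-mate with probability `boost`, swapping out a random
  non-planted identity so list length is preserved.
* **Planted dyads.** *Preferred*: if exactly one partner is held, the
  other is swapped in with probability `effect`. *Avoided*: if both are
  held, one is swapped out with probability `effect`. An avoided dyad
  inside one block is rejected as infeasible.
* **Behaviour profiles.** Each identity draws behaviours from a mixture:
  with probability `behaviour_overlap` from the shared population pool,
  otherwise from an identity-specific permuted pool; block-mates share
  their specific pool, so planted identity blocks also share behaviours
  (giving the identity-by-behaviour network correlated structure).

What the generator does **not** emulate: free-text coding noise,
identity entries with no behaviours (every synthetic entry lists ≥1, so
synthetic identity-by-behaviour matrices are denser than real ones),
demographic covariates, and any participant-level heterogeneity beyond
list length. Passing tests therefore demonstrate correctness of the
statistical machinery under realistic marginals, not fidelity to any
particular real survey's content.

## Problem sizes and test design

Oracle tests compare SRI matrices against double-loop counting (100 random
matrices), betweenness against exhaustive simple-path enumeration
(connected graphs ≤7 nodes, power-of-two weights so cost ties are exact),
and the two-clique walktrap optimum against enumeration of all 203
partitions of 6 nodes. Calibration runs 200 structureless surveys
(n = 286, 30-label vocabulary) with 1,000 permutations each; power runs 20
replicates per condition with 1,000 permutations and 3,000 proposal steps
between samples (extra mixing buys per-dyad resolution at small
permutation counts). The planted-dyad power condition uses a preferred
pair co-reported ≥15 times of 286 and an avoided pair of two frequent,
fully exclusive identities; the block condition uses two six-identity
blocks at boost 0.9 in a 30-label vocabulary.

## Known limitations

* The dyadic preferred/avoided test is conservative: dyad weights take few
  discrete values, and ties count toward both tails, so on structureless
  data the realized flag rate is ~1.5–2%, well under the nominal
  two-tailed 5%. Only mid-p or randomized variants would close that gap;
  both are deliberately avoided.
* Serial correlation between chain samples does not invalidate p-values
  (the anchored scheme is exact) but does reduce effective resolution;
  raising `swaps_per_permutation` sharpens dyad tests at linear cost.
* Betweenness under the default cost convention rewards *weak* edges with
  short paths; comparisons across weight modes are not meaningful, and the
  mode is always recorded in the output.
* Walktrap dendrograms can differ from other implementations on graphs
  with no clear community structure; only the well-separated regime is
  guaranteed to agree.
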