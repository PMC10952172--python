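# cooccurnet

Co-occurrence association networks from survey data.

People hold many social identities at once ("student", "daughter",
"scientist", ...), and each identity carries behaviours its members see as
typical. Given a survey in which each participant lists their group
memberships and, per group, the behaviours typical of its members, this
package asks population-level questions: which identities co-occur in the
same people more (or less) often than chance? Which behaviours are shared
across identities? Do identities that are shared also share behaviours?

The machinery is the one developed for animal social-network analysis,
applied to survey responses:

* **Occurrence matrices.** Each analysis starts from a binary
  samples-by-items matrix. For the *identity-by-identity* network a sample
  is a participant and the items are identities; for the
  *behaviour-by-identity* network a sample is a (participant, identity)
  response and the items are behaviours; for the *identity-by-behaviour*
  network a sample is a behaviour label and the items are identities.
  Nodes observed more than 3 times are retained (the frequency filter).
* **Simple Ratio Index edges.** The weight of the edge between items *A*
  and *B* is `SRI = x / (x + y_a + y_b)`, where *x* counts samples
  containing both and *y_a*, *y_b* samples containing only one — the
  proportion of samples involving either item in which the two co-occur.
* **Structure metrics.** Density `2E / (n(n-1))`, the coefficient of
  variation (CV) of dyad weights, weighted betweenness centrality, and
  walktrap communities (4-step random walks) scored by weighted Newman
  modularity `Q = Σ_c [w_in(c)/m − (s(c)/2m)²]`.
* **Datastream (Bejder) permutations.** A null model that holds fixed the
  number of samples, the items per sample and each item's total count,
  realized by margin-preserving 2×2 checkerboard swaps. The observed CV is
  compared with its null distribution (global non-randomness), and every
  dyad is classified *preferred* / *avoided* at a two-tailed α = .95
  (.975/.025 tails).
* **Mantel test.** Correlation between two association matrices on their
  shared nodes, with significance from simultaneous row/column
  relabelings.

A synthetic survey generator reproduces realistic marginals (286
participants; identities per participant with mean 5.20, SD 1.95 on 1–10;
behaviours per identity with mean 2.06, SD 1.26; heavy-tailed label
popularity over 138 identity and 83 behaviour labels) and can plant ground
truth: identity blocks, preferred/avoided dyads, and identity-specific
behaviour pools. Every stage of the pipeline is therefore testable with no
external data.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data:

```sh
python analysis/01_simulate_survey.py --seed 1   # draw the datasets
python analysis/02_build_networks.py             # occurrence -> SRI networks
python analysis/03_network_structure.py          # density, CV, modularity, betweenness
python analysis/04_permutation_tests.py          # global + dyad permutation tests
python analysis/05_mantel_correlation.py         # identity vs identity-by-behaviour
```

On the planted-structure dataset (two identity blocks, one preferred and
one avoided dyad, half-shared behaviour pools) this prints, among other
things:

```
identity_by_identity: 110 nodes unfiltered, 38 filtered, 370 edges
identity_by_identity: density 0.53, CV 2.28, modularity 0.36 (7 modules)
identity_by_identity: observed CV 2.280, global p 0.0001, 51 preferred and 64 avoided dyads of 703
Mantel: r = 0.616, n = 38 shared nodes, p = 0.0001
```

Read: after filtering, 38 identities remain; over half of all possible
identity pairs share at least one participant; the CV of edge weights is
far above its permutation null (global p ≈ .0001), so co-occurrence is not
random; 51 identity pairs co-occur significantly more often than chance
and 64 less often; and because planted blocks share behaviour pools, the
identity-by-identity and identity-by-behaviour networks correlate strongly
(r = .62). On the structureless companion dataset the same pipeline
reports global p spread uniformly and flags almost no dyads.

The same analysis is available as a CLI (`cooccurnet simulate`, `build`,
`analyze`, `report`) and as a library:

```python
from cooccurnet import (GeneratorConfig, generate, RunConfig, run,
                        PermutationConfig)

dataset, truth = generate(GeneratorConfig(seed=1))
result = run(RunConfig(permutation=PermutationConfig(n_permutations=10_000),
                       seed=1, out_dir="out"), dataset=dataset)
print(result.networks["identity_by_identity"].permutation.global_p)
```

## Layout

```
src/cooccurnet/     survey_io, occurrence, association, metrics,
                    nullmodels, matrix_tests, synthetic_data, pipeline, cli
analysis/           numbered narrative drivers (simulate -> mantel)
tests/              unit, property and acceptance tests
docs/methods.md     model, conventions, parameter choices, limitations
```
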