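# Methods

This note documents the models, parameters, numerical choices, and known
limitations of the `ickg` package, in the spirit of a model-description
appendix. It states nothing the test suite or `scripts/acceptance.py` does
not itself compute.

## Graph model

An ICKG is a directed multigraph. A node is keyed by `(name, node_type)`
with `node_type ∈ {gene, disease, cell_type, pathway, other}`; the same
string tagged with two different types yields two distinct nodes (no
precedence rule is imposed — both readings of the literature are kept).
Node names are case-fold merged within a type; gene names are normalized
through an alias table when one is supplied and reported as uppercase
symbols.

Between a source and a target there is at most one edge per sign, so an
activate and an inhibit edge may run in parallel. This deliberately
preserves disagreement in the literature rather than net-summing it; how
sign is consumed is a decision of the reasoning layer, not the assembly
layer. Edge weight equals the number of *distinct* abstracts supporting
the (source, target, sign) relation — duplicate statements within one
abstract do not inflate the weight — and the abstract ids are stored on
the edge (`provenance`), making Σ weights equal to the number of distinct
(source, target, sign, abstract) tuples by construction.

## Construction pipeline

**Tagging.** Taggers are a contract (`text → mentions`). The packaged
gazetteer tagger does case-insensitive whole-word matching; overlapping
mentions of the same type resolve to the longest span. Neural taggers can
be wrapped behind the same contract, but no trained model ships with the
package. NER evaluation supports two granularities behind a flag —
entity-level (exact span + type) and token-level (per word token, giving
partial credit to partial spans) — because published benchmarks are not
always explicit about which they use.

**Concept mining.** Sentences are chunked into candidate noun phrases.
The packaged chunker is rule-based: it tokenizes and breaks runs at stop
words, punctuation, and a lexicon of common verbs (inflected
automatically). It carries no part-of-speech model and therefore
over-generates on unknown verbs and adjectives; the lexical filters
downstream are responsible for discarding non-biomedical runs. Candidates
are kept when **any** of three filters fires: (1) normalized Levenshtein
similarity `1 − d/max(len)` ≥ 0.85 (configurable) to a controlled
vocabulary supplied as a local term list; (2) a biomedical suffix on the
final token (*ase, in, ion, itis, osis, oma, icity, pathy*) — the suffix
*in* is guarded to final tokens of length ≥ 4, because unguarded it
matches prepositions and floods the output; (3) a biomedical substring
anywhere in the phrase (*cell, gene, protein, receptor, antibody, immune,
tumor, cancer, virus, bacteria*). Which filters fired is recorded per
phrase. An optional reviewer backend (an LLM in production, a
deterministic mock in tests) may prune the survivors but can never add
terms: anything it returns that was not in the input is discarded with a
warning.

**Relation extraction.** Within each abstract, all `n(n−1)` ordered pairs
of distinct entities are enumerated (pairs never cross abstracts). A
versioned prompt template asks whether the first term activates, inhibits,
or has no association with the second, based only on the abstract, with
direction explicitly first→second. Response parsing takes the *first*
directional keyword in the reply and treats everything else — including
"no association" — as no relation, the safe default. Backend failures
skip the pair and continue. The deterministic mock backend answers from
`SOURCE trigger-verb TARGET` patterns with trigger verbs partitioned by
sign; the synthetic corpus generator draws only from those verbs, which is
what makes end-to-end recovery exact rather than approximate.

## Synthetic data

The corpus generator plants `n_relations` gene→gene/pathway relations and
emits one template abstract per (relation, supporting-abstract) pair —
sign-unambiguous verb, one relation per abstract, years uniform in
2020–2024 (the retention window used for corpus loading), cell-type tags
uniform over T/B/NK/macrophage. Fixed seeds reproduce the corpus byte for
byte. What it emulates: the support-count weighting, provenance tracking,
and directionality of real extraction. What it does not: tagger errors,
LLM misclassifications, multi-relation abstracts, anaphora, negation, or
literature bias. Passing the planted-recovery tests therefore certifies
the *pipeline plumbing* (enumeration, parsing, aggregation, weighting),
not extraction quality on real text.

The reasoning benchmark generator plants, among 50 genes and 10 pathway
nodes, (a) a hub gene activating 8 downstream genes with strong support
(weights 3–6) and (b) a pathway fed by 4 member genes (weights 3–5),
against ~80 weak background relations (weights 1–2, 70% activate). The
background never points into the planted pathway or out of the hub, so
the planted structure is signal and the background is the noise floor.
These sizes are desk-scale stand-ins for corpus-built graphs with
thousands of nodes; the contrast tested (planted wiring vs
degree-preserving shuffle) is scale-free in spirit, but absolute Jaccard
values on these graphs do not transfer to real corpora.

## Reasoning

**Personalized PageRank.** Damping α = 0.85 (default), restart vector
uniform over the seed set (absent a principled importance weighting,
uniform is the neutral choice), edge weights summed across
parallel signed edges as transition weights, dangling mass redistributed
to the restart vector. The solver is power iteration on a cached sparse
transition matrix with an absolute L1 convergence threshold of 1e−10
(max 1000 iterations; at α = 0.85 convergence takes ~150). Caching
matters because a permutation test performs thousands of solves that
differ only in the restart vector. Correctness is checked two independent
ways: against a dense numpy power-iteration oracle (L1 ≤ 1e−8 on graphs
up to 50 nodes) and against `networkx.pagerank`.

**Permutation significance.** Null seed sets are uniform same-size draws,
without replacement, from the graph's gene nodes. `p = n/N` with `n` the
permutations whose score ≥ observed — reported exactly as that ratio, so
`p = 0` is possible; the positively-biased `(n+1)/(N+1)` estimator is
available behind a flag. CIs are the 2.5th/97.5th percentiles of the null
score distribution. Calibration is verified against exhaustive
enumeration on a 6-gene graph (all 15 seed pairs) and by a
Kolmogorov–Smirnov uniformity check of 200 replicate p-values under an
exchangeable null.

**Adjusted random walk.** Transition probability from `u` to out-neighbor
`v` is `exp(w_uv/T) / Σ_x exp(w_ux/T)` (computed with max-subtraction for
overflow safety), defaults 1000 walks of 20 steps per start node, early
termination at sinks. Every node occupancy including the start counts as
a visit; frequencies are normalized to sum to 1. As `T → ∞` transitions
become uniform over out-neighbors; single-step sampling is verified
against the closed form by chi-square.

**Perturbation and explanation.** Perturbing a gene seeds PageRank on
that node alone; gene nodes receiving mass are ranked by score. Each
prediction carries one shortest path (by hop count) from the perturbed
gene; among equally short paths the one whose weakest edge is heaviest is
preferred, then lexicographic node order, both applied greedily per hop —
a deterministic choice, though the greedy lexicographic step is not
guaranteed globally lexicographic-minimal among all max-bottleneck paths.
Sign is the inhibit-edge parity of that path (even → activated, odd →
inhibited); when parallel signed edges join two consecutive path nodes,
the sign with the larger weight wins and a tie counts as activate.

**Concept association.** Association queries run PageRank on the
*reversed* graph by default (a `direction` parameter restores forward
propagation). Rationale: in ICKGs the literature predominantly asserts
gene → concept edges ("gene X activates cell type Y"), so the regulators
of a concept are its in-neighbors, which forward propagation from the
concept can never reach. Reversed propagation scores exactly the upstream
genes the query intends. Significance uses the same gene-pool permutation
null; a gene is associated when `p` is strictly below the threshold
(hence threshold 0 returns nothing by construction). Concept similarity
is the Jaccard index of associated gene sets.

**Shuffled-graph control.** "Random graph" is implemented as
degree-preserving rewiring — the stricter of the common null models —
via repeated target-swaps of edge pairs (10×|E| attempts), rejecting
self-loops and duplicate (source, target, sign) edges. Node types, weight
and sign multisets, and in-/out-degree sequences are preserved exactly.

## Evaluation layer

The directional confusion matrix is populated only by relation pairs
present in *both* prediction and reference, after alias normalization of
both endpoints; cells are A (both activate), B (predicted activate,
reference inhibit), C (predicted inhibit, reference activate), D (both
inhibit), with `P = A/(A+B)`, `R = A/(A+C)`, F1 harmonic, and zero
denominators giving 0. When one pair is predicted with both signs across
abstracts, the majority sign wins (ties → activate). KEGG interaction
subtypes are simplified with the fixed seven-entry table (three activation
subtypes, four inhibition subtypes); everything else is excluded.

GMM dichotomization fits `sklearn` GaussianMixture with 2 components and
a fixed seed to values sorted internally, so labels are invariant to
input order; it refuses fewer than 4 values or all-identical values.
PPI metrics are `networkx` density, average (unweighted) clustering, and
modularity of the greedy-modularity partition — the partition algorithm
is a documented choice, since only the metric is specified by the method
being implemented. Embedding coherence uses WCSS around the set centroid
and Euclidean centroid distances; the embedding backend is a contract, and
the packaged hashing embedder is deterministic but *not semantic* — it
exists so the geometry code is testable offline. PCA projection is
provided for plotting only and never affects metrics. Dispersion
comparisons (Levene, Mann–Whitney U) delegate to scipy.

## Numerical and environment notes

- Levenshtein distances come from `edlib`; the chunker is the rule-based
  component described above rather than a statistical parser.
- The Jaccard convention for two empty sets is 0. Overlap statements of
  the form "k of m reference genes recovered" do not determine a Jaccard
  value without the prediction-set size; this package always reports the
  standard |A∩B|/|A∪B| and never a recount-based approximation.
- Problem sizes in the verification suite — 100 random graphs ≤ 50 nodes,
  1000 Monte-Carlo draws vs 15 exhaustive subsets, 200 uniformity
  replicates at 200 permutations, 100 planted-graph seeds, 500
  permutations per annotation replicate — were chosen so the whole suite
  runs in about a minute on one CPU while keeping binomial/KS error well
  inside the asserted margins.

## Known limitations

- The rule chunker over-generates noun phrases; precision relies on the
  downstream lexical filters.
- The mock relation backend recognizes single-sentence
  subject–verb–object patterns only; it is a pipeline oracle, not an
  extraction model.
- Live backends (PubMed fetch, LLM relation endpoint) are contracts with
  minimal reference implementations and are never exercised by tests.
- Planted-graph benchmarks certify relative behavior (planted vs
  shuffled, observed vs null), not absolute performance on real corpora.
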