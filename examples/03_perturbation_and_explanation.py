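"""Predict the downstream targets of an in-silico gene perturbation.

Seeds personalized PageRank at a hub gene, ranks the other genes by the
mass they receive, signs each prediction by the inhibit-edge parity of its
shortest explanation path, and contrasts the recovery with a
degree-preserving shuffled control graph.
"""

from ickg import (
    generate_planted_reasoning_graph,
    in_silico_perturbation,
    jaccard_index,
    personalized_pagerank,
    shuffle_graph,
)

graph, truth = generate_planted_reasoning_graph(seed=13)
result = in_silico_perturbation(graph, truth.hub)

print(f"perturbed gene: {truth.hub}; planted targets: {sorted(truth.hub_targets)}")
print("top predictions (gene, score, inferred sign, explanation path):")
for gene, score, sign in result.ranked_genes[:8]:
    path = " -> ".join(n for n, _t in result.paths[gene])
    print(f"  {gene:<4} {score:.4f}  {sign:<9}  {path}")

top10 = {g for g, _s, _x in result.ranked_genes[:10]}
planted_j = jaccard_index(top10, truth.hub_targets)


def top10_on(g):
    scores = personalized_pagerank(g, [truth.hub])
    ranked = sorted((v for v in g.gene_nodes() if v[0] != truth.hub),
                    key=lambda v: (-scores[v], v))
    return {v[0] for v in ranked[:10]}


control_j = jaccard_index(top10_on(shuffle_graph(graph, seed=99)), truth.hub_targets)
print(f"Jaccard(top-10, planted targets): {planted_j:.3f} on the real graph "
      f"vs {control_j:.3f} on the shuffled control")
# A large gap means the prediction rests on the graph's actual wiring, not
# on degree structure alone.
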