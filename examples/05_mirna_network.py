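"""Build a miRNA-mRNA consensus target network.

A (miRNA, gene) pair is kept when at least 2 of 3 predictors agree; the
network then keeps only edges whose miRNA and gene are both responsive.
"""

from eretarget import DERecord, build_network, call_de, consensus_pairs
from eretarget.mirna_net import to_graph

predictions = {
    "miranda": {("miR-34b", "FOSB"), ("miR-34b", "EGR1"), ("miR-2954", "APOB")},
    "targetscan": {("miR-34b", "FOSB"), ("miR-2954", "APOB"), ("miR-2954", "JUN")},
    "pita": {("miR-34b", "FOSB"), ("miR-34b", "EGR1")},
}

pairs = consensus_pairs(predictions, min_votes=2)
for pair in pairs:
    print(f"consensus: {pair.mirna_id} -> {pair.gene_id} ({pair.votes}/3 votes)")

de = call_de([
    DERecord("miR-34b", "miRNA", 0.4, 0.01),   # down-regulated
    DERecord("miR-2954", "miRNA", 2.1, 0.02),  # up-regulated
    DERecord("FOSB", "mRNA", 1.8, 0.01),
    DERecord("EGR1", "mRNA", 0.2, 0.8),        # not responsive: excluded
    DERecord("APOB", "mRNA", 6.3, 0.001),
])

edges, nodes = build_network(pairs, de)
print("\nnetwork (responsive nodes only):")
for e in edges:
    print(f"  {e.mirna_id} ({e.mirna_direction}) -- {e.gene_id} ({e.gene_direction})")
graph = to_graph(edges, nodes)
print(f"bipartite graph: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges")
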