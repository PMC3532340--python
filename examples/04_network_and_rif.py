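"""Overlay DCGs on a TF->target map and rank regulators by RIF.

Builds the regulatory network (pairs with at least one DCG endpoint are
retained), classifies TFs as DCG-TFs versus TFs-of-DCGs, and ranks every
rankable TF by the regulatory impact factor. On planted data the module
anchors - the planted regulators - should head the ranking.
"""

from coexrif import (
    build_companions,
    build_network,
    classify_tfs,
    dcg_analysis,
    rank_tfs,
    simulate,
)
from coexrif.simulate import benchmark_spec

dataset, truth = simulate(benchmark_spec(seed=1))
_, pairs = build_companions(dataset, truth, n_decoy_tfs=20, seed=1)
result = dcg_analysis(dataset, n_perm=1000, seed=1)

network = build_network(
    result.dcgs, None, pairs,
    corr1=result.corr1, corr2=result.corr2, gene_index=dataset.gene_index(),
)
print(f"network: {len(network.edges)} edges among {len(network.nodes)} nodes "
      f"({len(network.tfs())} TFs)")
classes = classify_tfs(network)
print(classes["tf_class"].value_counts().to_string())
print()

ranked = rank_tfs(dataset, network, result.dcgs)
print("RIF ranking (|RIF| descending):")
print(ranked.head(5).to_string(index=False))
top = ranked.iloc[0]["tf"]
print(f"\ntop-ranked TF {top} is a planted regulator: {top in truth.planted_tfs()}")
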