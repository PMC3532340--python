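"""Hypergeometric pathway enrichment of a DCG list.

The detected DCGs are tested against the fixture's gene sets (two planted
module sets plus eight random decoy sets) with the measured genes as the
universe. The planted sets should dominate the ranking with tiny p-values;
the decoys should sit near p = 1.
"""

from coexrif import build_companions, dcg_analysis, enrich, simulate
from coexrif.simulate import benchmark_spec

dataset, truth = simulate(benchmark_spec(seed=1))
gene_sets, _ = build_companions(dataset, truth, seed=1)
result = dcg_analysis(dataset, n_perm=1000, seed=1)

table = enrich(result.dcgs, gene_sets, universe=set(dataset.gene_ids), alpha=0.05)
print(table.to_string(index=False))
print()
print("count = DCGs inside the set, size = measured genes in the set,")
print("p = hypergeometric upper-tail probability of seeing >= count by chance")
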