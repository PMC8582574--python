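"""Build a miRNA-mRNA inverse-correlation network and find its hubs.

Simulates a 60-sample dataset with three planted regulatory modules (one of
them fully isolated, sharing no targets with the rest), computes all-pairs
Spearman correlations, keeps pairs with rho < -0.4, filters to core miRNAs
regulating > 20 mRNAs, and reports the hub structure and centralities.
"""
import numpy as np

from mirnet import (
    SimConfig,
    build_bipartite,
    centralities,
    correlate_all,
    filter_core,
    filter_inverse,
    find_hubs,
    mirna_degree,
    project_unipartite,
    simulate_expression,
    summarize_network,
)

mirna, mrna, truth = simulate_expression(SimConfig(), seed=12)
rho = correlate_all(mirna, mrna)
edges = filter_inverse(rho, rho_max=-0.4)
network = build_bipartite(edges)
core = filter_core(network, min_degree=20)
hubs = find_hubs(core)
table = centralities(project_unipartite(core), mirna_degree(network))
summary = summarize_network(network, core, hubs, table)

print(f"edges below rho_max=-0.4 : {summary['total_edges']}")
print(f"miRNAs with >=1 edge     : {summary['total_mirnas']}")
print(f"core miRNAs (deg > 20)   : {summary['core_mirna_count']}"
      f"  carrying {summary['core_edge_share_pct']}% of all edges")
print(f"hubs (components)        : {len(hubs)}")
for i, hub in enumerate(hubs, 1):
    members = ", ".join(sorted(hub.member_mirnas))
    print(f"  hub {i}: {hub.edge_count} edges "
          f"({100 * hub.edge_fraction:.0f}% of core) | {members}")
print(f"planted isolated pair    : {', '.join(truth.isolated_mirnas)}")
print()
print("top centralities (eigenvector concentrates on the dominant hub;")
print("the isolated pair scores 0 there but keeps its own degree):")
print(table.sort_values("degree", ascending=False).round(3).to_string())
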