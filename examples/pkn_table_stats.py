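"""Summarizing a curated interaction table.

Parses the bundled synthetic 3-row prior-knowledge-network fixture and
prints its statistics: distinct nodes, directed edges (one per row),
distinct supporting PubMed IDs, and the confidence-class histogram.
"""

from sinboole import parse_interaction_table, pkn_statistics, skeleton_from_pkn
from sinboole.sin_model import synthetic_pkn_fixture

records = parse_interaction_table(synthetic_pkn_fixture())
stats = pkn_statistics(records)
print(f"{stats.n_nodes} nodes, {stats.n_edges} edges, {stats.n_pmids} distinct PMIDs")
print(f"confidence histogram: {stats.confidence_histogram}")
graph = skeleton_from_pkn(records)
for u, v, sign in graph.edges(data="sign"):
    print(f"  {u} {'-|' if sign == '-' else '->'} {v}")
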