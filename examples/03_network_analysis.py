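"""Degree distribution, hub detection and network simplification.

Works on the network from example 02 (rebuilding it if needed): computes
per-node degrees, finds the tie-inclusive top-fraction hubs, then removes
all non-candidate drug nodes and single-link nodes to expose the
target/gene/protein core, and assigns modules.
"""

import runpy
from pathlib import Path

from dtome import (
    assign_modules,
    degree_distribution,
    find_hubs,
    import_network,
    node_degrees,
    simplify_network,
)

if not Path("scratch/example_network.graphml").exists():
    runpy.run_path("examples/02_build_drug_network.py")

net = import_network("scratch/example_network.graphml", "graphml")
table = node_degrees(net)
dist = degree_distribution(table)
print(f"{len(table)} nodes; max degree {table['degree'].max()}; "
      f"{dist.get(1, 0)} nodes have a single link")

hubs = find_hubs(table, fraction=0.05)
print(f"hub threshold degree {hubs.threshold_degree}; {len(hubs.hubs)} hubs "
      f"(top-5%: the right tail of the degree distribution)")

simplified, report = simplify_network(net, ["DB00001"])
print(
    f"simplification removed {report.n_drugs_removed} non-candidate drugs and "
    f"{report.n_low_degree_removed} single-link nodes; "
    f"{simplified.graph.number_of_nodes()} nodes remain"
)
modules = assign_modules(simplified)
print(f"{len(set(modules.values()))} connected module(s) in the simplified core")
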