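"""Build the four-relation interactome for one candidate drug.

Loads the knowledge base, extracts adverse drug interactions (DDI),
drug-target edges (DT), drug-gene associations (DG) and the first-neighbor
protein interactions (PPI) around targets and genes, merges them into one
typed network and exports it for Cytoscape-style tools.
"""

from pathlib import Path

from dtome import (
    KnowledgeBase,
    SynthParams,
    build_dtome,
    export_network,
    generate_knowledge_base,
    get_ddi,
    get_first_neighbors,
    get_genes,
    get_targets,
)

kb_dir = Path("scratch/example_kb")
if not (kb_dir / "drugs.xml").exists():
    generate_knowledge_base(SynthParams(rng_seed=7), kb_dir)

kb = KnowledgeBase.load(
    drug_xml=kb_dir / "drugs.xml",
    associations_tsv=kb_dir / "associations.tsv",
    ppi_mitab=kb_dir / "ppi.mitab",
    idmap_tsv=kb_dir / "idmap.tsv",
)

candidate = "DB00001"
ddi = get_ddi(kb, [candidate])
dt = get_targets(kb, [candidate])
dg = get_genes(kb, [candidate])
seeds = {e.symbol for e in dt.edges} | {e.symbol for e in dg.edges}
ppi = get_first_neighbors(kb.ppi, seeds)

net = build_dtome([candidate], ddi.edges, dt.edges, dg.edges, ppi)
summary = net.summary()
print("node roles:", summary["roles"])
print("edge relations:", summary["relations"])
# target_and_gene counts genes that are simultaneously a documented target
# and a pharmacogenomically associated gene of the candidate.

export_network(net, "scratch/example_network.graphml", "graphml")
export_network(net, "scratch/example_network.sif", "sif")
print("exported scratch/example_network.{graphml,sif}")
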