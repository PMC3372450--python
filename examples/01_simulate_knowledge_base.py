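"""Generate a synthetic drug/gene/protein knowledge base with a manifest.

The generator writes the six files the workflow consumes (drug XML,
drug-gene associations, PSI-MI TAB interactions, an AC->GeneID->symbol
map, an ATC code table, a GMT gene-set collection) plus a manifest of the
counts every downstream stage should reproduce.
"""

import json
from pathlib import Path

from dtome import SynthParams, generate_knowledge_base

out = Path("scratch/example_kb")
paths, manifest = generate_knowledge_base(SynthParams(rng_seed=7), out)

print(f"wrote {len(paths)} files into {out}/")
cand = manifest["candidate"]
print(
    f"candidate {cand['drugbank_id']} ({cand['name']}): "
    f"{cand['n_ddi']} adverse interactions, {cand['n_targets']} targets, "
    f"{cand['n_assoc_genes']} associated genes ({cand['n_overlap']} overlap both)"
)
print("planted PPI filter exclusions:", json.dumps(manifest["ppi"]["excluded"]))
# The manifest is the ground truth: parsing and filtering these files must
# reproduce exactly these numbers, which is what the test suite asserts.
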