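import pytest

from dtome import (
    DrugRecord,
    IdMap,
    KnowledgeBase,
    SynthParams,
    generate_knowledge_base,
)
from dtome.kb_io import link_drug_vocabularies
from dtome.netbuild import build_dtome, get_ddi, get_first_neighbors, get_genes, get_targets


@pytest.fixture(scope="session")
def synth_kb(tmp_path_factory):
    """Default-profile synthetic knowledge base: (paths, manifest)."""
    out = tmp_path_factory.mktemp("synth_kb")
    return generate_knowledge_base(SynthParams(rng_seed=7), out)


@pytest.fixture(scope="session")
def kb_paths(synth_kb):
    return synth_kb[0]


@pytest.fixture(scope="session")
def manifest(synth_kb):
    return synth_kb[1]


@pytest.fixture(scope="session")
def kb(kb_paths) -> KnowledgeBase:
    return KnowledgeBase.load(
        drug_xml=kb_paths["drug_xml"],
        associations_tsv=kb_paths["associations"],
        ppi_mitab=kb_paths["ppi_mitab"],
        idmap_tsv=kb_paths["idmap"],
    )


@pytest.fixture(scope="session")
def candidate_network(kb, manifest):
    """The candidate drug's full four-relation network from the synth fixture."""
    cand = manifest["candidate"]["drugbank_id"]
    ddi = get_ddi(kb, [cand])
    dt = get_targets(kb, [cand])
    dg = get_genes(kb, [cand])
    seeds = {e.symbol for e in dt.edges} | {e.symbol for e in dg.edges}
    ppi = get_first_neighbors(kb.ppi, seeds)
    return build_dtome([cand], ddi.edges, dt.edges, dg.edges, ppi)


def make_kb(drugs, associations=(), ppi=(), idmap=None) -> KnowledgeBase:
    """Assemble a small in-memory knowledge base for unit tests."""
    drug_list = list(drugs)
    idmap = idmap if idmap is not None else IdMap()
    link = link_drug_vocabularies(drug_list, list(associations))
    return KnowledgeBase(
        drugs={d.drugbank_id: d for d in drug_list},
        associations=list(associations),
        ppi=list(ppi),
        idmap=idmap,
        drug_link=link,
    )


def simple_drug(drugbank_id, name, **kwargs) -> DrugRecord:
    kwargs.setdefault("groups", frozenset({"approved"}))
    return DrugRecord(drugbank_id=drugbank_id, name=name, **kwargs)
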