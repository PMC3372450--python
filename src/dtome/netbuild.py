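"""Query the knowledge base and assemble a typed drug-target interactome.

A drug-target interactome joins one or more candidate drugs to four kinds
of relation: adverse drug-drug interactions (DDI), drug-target interactions
(DT), pharmacogenomic drug-gene associations (DG), and the protein-protein
interactions (PPI) recruiting the direct interactors of targets and
associated genes. Node roles distinguish candidate drugs, interacting
drugs, targets, associated genes, genes that are both (a distinct class),
and PPI-recruited interactor proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import ValidationError
from .kb_io import KnowledgeBase, PPIEdge, map_ac_to_symbol

ROLES = (
    "candidate_drug",
    "interacting_drug",
    "target",
    "associated_gene",
    "target_and_gene",
    "interactor_protein",
)
DRUG_ROLES = frozenset({"candidate_drug", "interacting_drug"})
RELATIONS = ("DDI", "DT", "DG", "PPI")


# ---------------------------------------------------------------------------
# Edge records produced by the extraction operations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DDIEdge:
    drug_id: str
    partner_id: str
    description: str = ""
    partner_in_kb: bool = True


@dataclass(frozen=True)
class DTEdge:
    drug_id: str
    symbol: str


@dataclass(frozen=True)
class DGEdge:
    drug_id: str
    symbol: str
    evidence: frozenset = frozenset()


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

@dataclass
class DrugQuery:
    """Search over drug name / category / group / indication, AND-combined."""

    name: str | None = None
    name_mode: str = "whole"  # "whole" or "partial"
    category: str | None = None
    group: str | None = None
    indication: str | None = None

    def validate(self) -> None:
        if not any((self.name, self.category, self.group, self.indication)):
            raise ValidationError("empty drug query: set at least one field")
        if self.name_mode not in ("whole", "partial"):
            raise ValidationError(f"unknown name mode {self.name_mode!r}")


@dataclass
class DrugSummary:
    drugbank_id: str
    name: str
    groups: frozenset
    categories: list
    n_ddi: int
    n_targets: int
    n_genes: int
    indication: str


def _matches(drug, query: DrugQuery) -> bool:
    if query.name is not None:
        needle = query.name.lower().strip()
        names = [drug.name.lower(), *(s.lower() for s in drug.synonyms)]
        if query.name_mode == "whole":
            if needle not in names:
                return False
        else:
            if not any(needle in n for n in names):
                return False
    if query.category is not None:
        needle = query.category.lower()
        if not any(needle in c.lower() for c in drug.categories):
            return False
    if query.group is not None:
        if query.group.lower() not in drug.groups:
            return False
    if query.indication is not None:
        if query.indication.lower() not in drug.indication.lower():
            return False
    return True


def _association_genes(kb: KnowledgeBase, drug_id: str) -> set[str]:
    sid = kb.drug_link.db_to_src.get(drug_id)
    if sid is None:
        return set()
    return {a.gene_symbol for a in kb.associations if a.source_drug_id == sid}


def search_drugs(kb: KnowledgeBase, query: DrugQuery) -> list[DrugSummary]:
    """Case-insensitive AND-combined search returning per-drug summaries.

    Counts in each summary are recomputed from the knowledge base: distinct
    interaction partners, distinct mapped target symbols, distinct linked
    association genes.
    """
    query.validate()
    summaries = []
    for did in sorted(kb.drugs):
        drug = kb.drugs[did]
        if not _matches(drug, query):
            continue
        mapped, _ = map_ac_to_symbol(drug.target_acs, kb.idmap)
        summaries.append(
            DrugSummary(
                drugbank_id=did,
                name=drug.name,
                groups=drug.groups,
                categories=list(drug.categories),
                n_ddi=len({pid for pid, _ in drug.ddi_partners}),
                n_targets=len(set(mapped.values())),
                n_genes=len(_association_genes(kb, did)),
                indication=drug.indication,
            )
        )
    return summaries


# ---------------------------------------------------------------------------
# Extraction operations
# ---------------------------------------------------------------------------

@dataclass
class DDIResult:
    edges: list[DDIEdge]
    n_interactions: int
    n_query_drugs_matched: int
    n_partner_drugs: int


def get_ddi(kb: KnowledgeBase, drug_ids) -> DDIResult:
    """Adverse interaction edges for the given drugs, with the summary
    triple (interaction count, matched query drugs, distinct partners)."""
    seen: set[tuple[str, str]] = set()
    edges: list[DDIEdge] = []
    matched = 0
    for did in drug_ids:
        drug = kb.get_drug(did)
        matched += 1
        for pid, desc in drug.ddi_partners:
            key = (did, pid)
            if key in seen:
                continue
            seen.add(key)
            edges.append(
                DDIEdge(
                    drug_id=did,
                    partner_id=pid,
                    description=desc,
                    partner_in_kb=pid in kb.drugs,
                )
            )
    partners = {e.partner_id for e in edges}
    return DDIResult(
        edges=edges,
        n_interactions=len(edges),
        n_query_drugs_matched=matched,
        n_partner_drugs=len(partners),
    )


@dataclass
class TargetResult:
    edges: list[DTEdge]
    unmapped: dict[str, list[str]]


def get_targets(kb: KnowledgeBase, drug_ids) -> TargetResult:
    """Drug-target edges with target accessions translated to gene symbols."""
    edges: list[DTEdge] = []
    unmapped: dict[str, list[str]] = {}
    for did in drug_ids:
        drug = kb.get_drug(did)
        mapped, missing = map_ac_to_symbol(drug.target_acs, kb.idmap)
        if missing:
            unmapped[did] = missing
        for sym in sorted(set(mapped.values())):
            edges.append(DTEdge(drug_id=did, symbol=sym))
    return TargetResult(edges=edges, unmapped=unmapped)


@dataclass
class GeneResult:
    edges: list[DGEdge]
    warnings: list[str]


def get_genes(kb: KnowledgeBase, drug_ids) -> GeneResult:
    """Drug-gene association edges joined through the vocabulary link."""
    edges: list[DGEdge] = []
    warnings: list[str] = []
    for did in drug_ids:
        kb.get_drug(did)
        sid = kb.drug_link.db_to_src.get(did)
        if sid is None:
            warnings.append(f"drug {did} has no pharmacogenomic link; 0 gene edges")
            continue
        by_gene: dict[str, set[str]] = {}
        for a in kb.associations:
            if a.source_drug_id == sid:
                by_gene.setdefault(a.gene_symbol, set()).update(a.evidence)
        for sym in sorted(by_gene):
            edges.append(DGEdge(drug_id=did, symbol=sym, evidence=frozenset(by_gene[sym])))
    return GeneResult(edges=edges, warnings=warnings)


def get_first_neighbors(ppi_edges, seeds) -> list[PPIEdge]:
    """PPI edges with at least one endpoint in the seed symbol set."""
    seed_set = {s.upper() for s in seeds}
    return [e for e in ppi_edges if e.symbol_a in seed_set or e.symbol_b in seed_set]


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------

class DTomeNetwork:
    """Typed multi-relation interactome over an undirected multigraph.

    One edge per (unordered node pair, relation); a pair may carry several
    relations (e.g. DT and DG to the same gene are distinct edges). Node
    roles are single-valued.
    """

    def __init__(self, graph: nx.MultiGraph | None = None):
        self.graph = graph if graph is not None else nx.MultiGraph()

    # -- construction -------------------------------------------------
    def add_node(self, node_id: str, role: str | None = None, **attrs) -> None:
        if role is not None and role not in ROLES:
            raise ValidationError(f"unknown node role {role!r}")
        self.graph.add_node(node_id, role=role, **attrs)

    def add_edge(self, a: str, b: str, relation: str, sources=()) -> None:
        if relation not in RELATIONS:
            raise ValidationError(f"unknown edge relation {relation!r}")
        for n in (a, b):
            if n not in self.graph:
                self.graph.add_node(n, role=None)
        if self.graph.has_edge(a, b, key=relation):
            existing = self.graph.edges[a, b, relation].get("sources", ())
            merged = tuple(sorted(set(existing) | set(sources)))
            self.graph.edges[a, b, relation]["sources"] = merged
        else:
            self.graph.add_edge(a, b, key=relation, sources=tuple(sorted(set(sources))))

    # -- views ---------------------------------------------------------
    @property
    def node_roles(self) -> dict[str, str | None]:
        return {n: d.get("role") for n, d in self.graph.nodes(data=True)}

    def edge_records(self) -> list[tuple[str, str, str, tuple[str, ...]]]:
        out = []
        for a, b, rel, data in self.graph.edges(keys=True, data=True):
            lo, hi = sorted((a, b))
            out.append((lo, hi, rel, tuple(data.get("sources", ()))))
        return sorted(out)

    def edge_set(self) -> set[tuple[str, str, str]]:
        return {(a, b, rel) for a, b, rel, _ in self.edge_records()}

    def role_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in ROLES}
        for _, role in self.node_roles.items():
            if role is not None:
                counts[role] += 1
        return counts

    def relation_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in RELATIONS}
        for _, _, rel in self.graph.edges(keys=True):
            counts[rel] += 1
        return counts

    def summary(self) -> dict:
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            "roles": self.role_counts(),
            "relations": self.relation_counts(),
        }

    def copy(self) -> "DTomeNetwork":
        return DTomeNetwork(self.graph.copy())

    def __contains__(self, node_id) -> bool:
        return node_id in self.graph

    def __eq__(self, other) -> bool:
        if not isinstance(other, DTomeNetwork):
            return NotImplemented
        return (
            self.node_roles == other.node_roles
            and self.edge_set() == other.edge_set()
        )


def build_dtome(
    candidates,
    ddi_edges=(),
    dt_edges=(),
    dg_edges=(),
    ppi_edges=(),
) -> DTomeNetwork:
    """Merge the four relation types into one typed network.

    Role assignment: candidates -> candidate_drug; DDI partners ->
    interacting_drug; DT endpoints -> target; DG endpoints ->
    associated_gene; genes with both DT and DG edges -> target_and_gene;
    remaining PPI endpoints -> interactor_protein. Drug ids and gene
    symbols live in disjoint namespaces; a clash is an error.
    """
    candidates = list(candidates)
    cand = set(candidates)
    ddi_edges = list(ddi_edges)
    dt_edges = list(dt_edges)
    dg_edges = list(dg_edges)
    ppi_edges = list(ppi_edges)

    drug_ids = set(cand)
    drug_ids.update(e.drug_id for e in ddi_edges)
    drug_ids.update(e.partner_id for e in ddi_edges)
    drug_ids.update(e.drug_id for e in dt_edges)
    drug_ids.update(e.drug_id for e in dg_edges)

    dt_syms = {e.symbol for e in dt_edges}
    dg_syms = {e.symbol for e in dg_edges}
    ppi_syms = {s for e in ppi_edges for s in (e.symbol_a, e.symbol_b)}
    gene_ids = dt_syms | dg_syms | ppi_syms

    clash = drug_ids & gene_ids
    if clash:
        raise ValidationError(
            f"identifiers used both as drug id and gene symbol: {sorted(clash)}"
        )

    stub_partners = {e.partner_id for e in ddi_edges if not e.partner_in_kb} - cand

    net = DTomeNetwork()
    for did in sorted(drug_ids):
        role = "candidate_drug" if did in cand else "interacting_drug"
        net.add_node(did, role=role, stub=(did in stub_partners))
    for sym in sorted(gene_ids):
        if sym in dt_syms and sym in dg_syms:
            role = "target_and_gene"
        elif sym in dt_syms:
            role = "target"
        elif sym in dg_syms:
            role = "associated_gene"
        else:
            role = "interactor_protein"
        net.add_node(sym, role=role)

    for e in sorted(ddi_edges, key=lambda e: (e.drug_id, e.partner_id)):
        net.add_edge(e.drug_id, e.partner_id, "DDI", sources=("drug_knowledge",))
    for e in sorted(dt_edges, key=lambda e: (e.drug_id, e.symbol)):
        net.add_edge(e.drug_id, e.symbol, "DT", sources=("drug_knowledge",))
    for e in sorted(dg_edges, key=lambda e: (e.drug_id, e.symbol)):
        net.add_edge(e.drug_id, e.symbol, "DG", sources=("pharmacogenomic",))
    for e in sorted(ppi_edges, key=lambda e: (e.symbol_a, e.symbol_b)):
        net.add_edge(e.symbol_a, e.symbol_b, "PPI", sources=e.sources or ("ppi",))
    return net


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

_FORMATS = {"sif", "graphml", "tsv"}


def export_network(net: DTomeNetwork, path, fmt: str = "graphml") -> None:
    """Write the network as SIF, GraphML (lossless) or a 4-column TSV edge list."""
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValidationError(f"unknown export format {fmt!r}; choose from {sorted(_FORMATS)}")
    records = net.edge_records()
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b, rel, _ in records:
                fh.write(f"{a}\t{rel}\t{b}\n")
        return
    if fmt == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b, rel, sources in records:
                fh.write(f"{a}\t{rel}\t{b}\t{'|'.join(sources)}\n")
        return
    g = nx.MultiGraph()
    for n in sorted(net.graph.nodes):
        d = net.graph.nodes[n]
        g.add_node(n, role=d.get("role") or "", stub=bool(d.get("stub", False)))
    for a, b, rel, sources in records:
        g.add_edge(a, b, key=rel, relation=rel, sources="|".join(sources))
    nx.write_graphml(g, path)


def import_network(path, fmt: str = "graphml") -> DTomeNetwork:
    """Rebuild a network from a GraphML or TSV export.

    GraphML restores roles and provenance exactly; the TSV edge list
    carries no roles, so imported nodes have role ``None``.
    """
    fmt = fmt.lower()
    if fmt == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        net = DTomeNetwork()
        for n, d in g.nodes(data=True):
            role = d.get("role") or None
            net.add_node(str(n), role=role, stub=bool(d.get("stub", False)))
        for a, b, _, d in g.edges(keys=True, data=True):
            rel = d.get("relation")
            sources = tuple(s for s in (d.get("sources") or "").split("|") if s)
            net.add_edge(str(a), str(b), rel, sources=sources)
        return net
    if fmt == "tsv":
        net = DTomeNetwork()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                a, rel, b, sources = line.split("\t")
                net.add_edge(a, b, rel, sources=tuple(s for s in sources.split("|") if s))
        return net
    raise ValidationError(f"unsupported import format {fmt!r}; use graphml or tsv")
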