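"""Synthetic miniature knowledge base with a ground-truth manifest.

Generates all six input files the workflow consumes — drug XML,
drug-gene association TSV, PSI-MI TAB PPIs, AC/GeneID/symbol map, ATC
table, GMT gene sets — together with a machine-readable manifest of every
count the downstream parsers, filters and builders are expected to
produce. The default profile mirrors a well-characterised single-drug
interactome: a candidate with 54 adverse drug interactions, 26 primary
targets and 51 associated genes, 16 of which are both target and
associated gene, and an interacting-drug ATC composition dominated by
nervous-system drugs (41 of 54).

All randomness flows through one ``random.Random(rng_seed)``; generation
is byte-deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import random
from collections import Counter, defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import ValidationError
from .kb_io import (
    DEFAULT_SALT_SUFFIXES,
    DrugRecord,
    write_associations,
    write_atc_table,
    write_drug_xml,
    write_idmap,
)

_EXPERIMENTAL_METHODS = (
    'psi-mi:"MI:0018"(two hybrid)',
    'psi-mi:"MI:0006"(anti bait coimmunoprecipitation)',
    'psi-mi:"MI:0114"(x-ray crystallography)',
    'psi-mi:"MI:0096"(pull down)',
)
_PREDICTED_METHOD = 'psi-mi:"MI:0063"(interaction prediction)'
_SOURCE_DBS = (
    'psi-mi:"MI:0469"(intact)',
    'psi-mi:"MI:0471"(mint)',
    'psi-mi:"MI:0463"(biogrid)',
    'psi-mi:"MI:0465"(dip)',
    'psi-mi:"MI:0468"(hprd)',
    'psi-mi:"MI:0464"(mips)',
)

#: Level-3 ATC composition planted over the interacting drugs
#: (nervous-system heavy, as in a typical antipsychotic's DDI profile).
DEFAULT_ATC_COMPOSITION = {
    "N05B": 11,
    "N05C": 9,
    "N03A": 7,
    "N06A": 5,
    "N05A": 4,
    "N02A": 3,
    "N06B": 1,
    "N07X": 1,
    "J01A": 4,
    "J01C": 2,
    "A02B": 3,
    "C07A": 2,
    "R06A": 2,
}

_CATEGORY_BY_PREFIX = {
    "N02A": "analgesic",
    "N03A": "antiepileptic",
    "N05A": "antipsychotic",
    "N05B": "anxiolytic",
    "N05C": "hypnotic and sedative",
    "N06A": "antidepressant",
    "N06B": "psychostimulant",
    "N07X": "other nervous system drug",
    "J01A": "antibacterial",
    "J01C": "antibacterial",
    "A02B": "drug for peptic ulcer",
    "C07A": "beta blocking agent",
    "R06A": "antihistamine",
}

_INDICATIONS = (
    "schizophrenia",
    "epilepsy",
    "bacterial infection",
    "anxiety disorder",
    "insomnia",
    "major depression",
    "chronic pain",
    "allergic rhinitis",
    "peptic ulcer",
    "hypertension",
)

_AMBIGUOUS_SYNONYMS = ("Ambidrug Alpha", "Ambidrug Beta", "Ambidrug Gamma", "Ambidrug Delta")


@dataclass
class SynthParams:
    """Study conditions for the generated knowledge base (see module docs)."""

    n_drugs: int = 60
    n_candidate: int = 1
    n_ddi_per_candidate: int = 54
    n_targets_per_candidate: int = 26
    n_assoc_per_candidate: int = 51
    n_overlap: int = 16
    n_proteins: int = 300
    ppi_edge_count: int = 800
    hub_bias: float = 0.3
    planted_self_loops: int = 20
    planted_nonhuman: int = 30
    planted_predicted_only: int = 25
    planted_duplicates: int = 10
    planted_unmapped: int = 10
    idmap_hole_rate: float = 0.05
    n_stage1_links: int = 10
    n_stage2_links: int = 5
    n_ambiguous_links: int = 2
    n_invalid_assoc: int = 5
    atc_composition: dict = field(default_factory=lambda: dict(DEFAULT_ATC_COMPOSITION))
    category_plants: dict = field(default_factory=lambda: {"anticonvulsant": 4})
    gene_set_count: int = 10
    gene_set_size: int = 40
    planted_enriched_set_overlap: int = 20
    rng_seed: int = 7

    def validate(self) -> None:
        counts = {
            k: v
            for k, v in asdict(self).items()
            if isinstance(v, int) and k != "rng_seed"
        }
        bad = {k: v for k, v in counts.items() if v < 0}
        if bad:
            raise ValidationError(f"negative counts in parameters: {bad}")
        if not 0 <= self.idmap_hole_rate <= 1:
            raise ValidationError("idmap_hole_rate must be in [0, 1]")
        if not 0 <= self.hub_bias <= 1:
            raise ValidationError("hub_bias must be in [0, 1]")
        if self.n_overlap > min(self.n_targets_per_candidate, self.n_assoc_per_candidate):
            raise ValidationError(
                "n_overlap cannot exceed min(n_targets_per_candidate, n_assoc_per_candidate)"
            )
        if self.n_candidate != 1:
            raise ValidationError("the generator plants exactly one candidate drug")
        n_extra = self.n_drugs - self.n_candidate - self.n_ddi_per_candidate
        if n_extra < 2 * self.n_ambiguous_links + 1:
            raise ValidationError(
                "n_drugs too small for the planted ambiguous links and dangling partner"
            )
        if self.n_ambiguous_links > len(_AMBIGUOUS_SYNONYMS):
            raise ValidationError("too many ambiguous links requested")
        if self.n_stage1_links + self.n_stage2_links > 1 + self.n_ddi_per_candidate:
            raise ValidationError("not enough drugs to host the planted links")
        if sum(self.atc_composition.values()) != self.n_ddi_per_candidate:
            raise ValidationError(
                "atc_composition counts must sum to n_ddi_per_candidate"
            )
        if self.n_targets_per_candidate + self.n_assoc_per_candidate > self.n_proteins:
            raise ValidationError("protein universe too small for targets + genes")
        if self.ppi_edge_count > self.n_proteins * (self.n_proteins - 1) // 2:
            raise ValidationError("ppi_edge_count exceeds the simple-graph maximum")


@dataclass
class PPIGraph:
    edges: list[tuple[str, str]]
    hub: str
    degrees: dict[str, int]


def generate_ppi_graph(
    n_proteins: int,
    edge_count: int,
    hub_bias: float = 0.3,
    seed: int | None = None,
    rng: random.Random | None = None,
    labels=None,
) -> PPIGraph:
    """Simple undirected graph with one designated strictly-highest-degree hub.

    A fraction ``hub_bias`` of the edges attaches to the hub; the rest are
    uniform among the other nodes. Raises if the construction cannot
    guarantee the hub's strict maximality.
    """
    rng = rng if rng is not None else random.Random(seed)
    if labels is None:
        labels = [f"G{i + 1:04d}" for i in range(n_proteins)]
    labels = list(labels)
    n = len(labels)
    if n != n_proteins:
        raise ValidationError("labels length must equal n_proteins")
    if edge_count > n * (n - 1) // 2:
        raise ValidationError(f"edge_count {edge_count} infeasible for {n} nodes")
    if n < 2 or edge_count < 1:
        raise ValidationError("need at least 2 nodes and 1 edge")

    hub = labels[rng.randrange(n)]
    others = [x for x in labels if x != hub]
    k_hub = min(n - 1, max(1, round(hub_bias * edge_count)), edge_count)
    partners = rng.sample(others, k_hub)
    edges = {tuple(sorted((hub, p))) for p in partners}

    rest = edge_count - k_hub
    max_rest = (n - 1) * (n - 2) // 2
    if rest > max_rest:
        raise ValidationError("edge_count infeasible once the hub edges are placed")
    attempts = 0
    while len(edges) < edge_count:
        a, b = rng.sample(others, 2)
        key = tuple(sorted((a, b)))
        if key not in edges:
            edges.add(key)
        attempts += 1
        if attempts > 100 * edge_count + 1000:
            raise ValidationError("edge sampling stalled; lower edge_count or raise n_proteins")

    degrees: dict[str, int] = defaultdict(int)
    for a, b in edges:
        degrees[a] += 1
        degrees[b] += 1
    max_other = max((d for x, d in degrees.items() if x != hub), default=0)
    if degrees[hub] <= max_other:
        raise ValidationError(
            f"hub_bias {hub_bias} too low to guarantee a unique hub "
            f"(hub degree {degrees[hub]}, max other {max_other})"
        )
    return PPIGraph(edges=sorted(edges), hub=hub, degrees=dict(degrees))


def _mitab_line(ac_a, ac_b, method, tax_a, tax_b, source) -> str:
    cols = [
        f"uniprotkb:{ac_a}",
        f"uniprotkb:{ac_b}",
        "-",
        "-",
        "-",
        "-",
        method,
        "-",
        "pubmed:12345678",
        tax_a,
        tax_b,
        'psi-mi:"MI:0915"(physical association)',
        source,
        "-",
        "-",
    ]
    return "\t".join(cols)


_HUMAN = "taxid:9606(Homo sapiens)"
_MOUSE = "taxid:10090(Mus musculus)"


def generate_knowledge_base(params: SynthParams, out_dir) -> tuple[dict, dict]:
    """Write the six input files plus ``manifest.json`` into ``out_dir``.

    Returns ``(paths, manifest)``. The manifest records the expected output
    of every downstream stage (parser counts, filter exclusions by reason,
    link stages, network node/edge/role totals, simplification removals,
    ATC composition, planted hub and enriched set), computed here by
    independent construction-time bookkeeping.
    """
    params.validate()
    p = params
    rng = random.Random(p.rng_seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- identifier universe -------------------------------------------
    symbols = [f"G{i + 1:04d}" for i in range(p.n_proteins)]
    ac_of = {s: f"P{10001 + i}" for i, s in enumerate(symbols)}
    geneid_of = {s: str(1001 + i) for i, s in enumerate(symbols)}
    n_holes = round(p.idmap_hole_rate * p.n_proteins)
    hole_acs = [f"Q{20001 + i}" for i in range(n_holes)]
    idmap_rows = [(ac_of[s], geneid_of[s], s) for s in symbols]
    for i, ha in enumerate(hole_acs):
        # alternate the two failure modes: no gene id / gene id without symbol
        idmap_rows.append((ha, "", "") if i % 2 == 0 else (ha, str(9001 + i), ""))

    # ---- PPI graph ------------------------------------------------------
    graph = generate_ppi_graph(
        p.n_proteins, p.ppi_edge_count, p.hub_bias, rng=rng, labels=symbols
    )
    edge_set = set(graph.edges)

    # ---- candidate gene sets -------------------------------------------
    target_syms = sorted(rng.sample(symbols, p.n_targets_per_candidate))
    overlap_syms = sorted(rng.sample(target_syms, p.n_overlap))
    non_target = [s for s in symbols if s not in set(target_syms)]
    assoc_only = sorted(rng.sample(non_target, p.n_assoc_per_candidate - p.n_overlap))
    assoc_syms = sorted(set(overlap_syms) | set(assoc_only))

    # ---- drugs ----------------------------------------------------------
    n_inter = p.n_ddi_per_candidate
    n_extra = p.n_drugs - 1 - n_inter
    drug_ids = [f"DB{i + 1:05d}" for i in range(p.n_drugs)]
    cand_id, inter_ids = drug_ids[0], drug_ids[1 : 1 + n_inter]
    extra_ids = drug_ids[1 + n_inter :]

    atc_prefixes: list[str] = []
    for prefix in sorted(p.atc_composition):
        atc_prefixes.extend([prefix] * p.atc_composition[prefix])

    records: list[DrugRecord] = []
    records.append(
        DrugRecord(
            drugbank_id=cand_id,
            name="drug001",
            synonyms=["Drug001 Hydrochloride"],
            groups=frozenset({"approved"}),
            categories=["antipsychotic"],
            indication="schizophrenia",
            atc_codes=["N05AH02"],
            ddi_partners=[
                (pid, f"Increased risk of adverse effects when combined with drug001.")
                for pid in inter_ids
            ],
            target_acs=[ac_of[s] for s in target_syms],
            external_links=[("PharmGKB", "PA90001")],
        )
    )

    stage1_ids = inter_ids[: p.n_stage1_links - 1]  # candidate is the other stage-1 link
    stage2_ids = inter_ids[p.n_stage1_links - 1 : p.n_stage1_links - 1 + p.n_stage2_links]
    plant_pool = []
    for cat, count in sorted(p.category_plants.items()):
        plant_pool.extend([cat] * count)

    for j, did in enumerate(inter_ids):
        num = int(did[2:])
        name = f"drug{num:03d}"
        prefix = atc_prefixes[j]
        code = f"{prefix}A{(j % 99) + 1:02d}"
        category = _CATEGORY_BY_PREFIX.get(prefix, "miscellaneous")
        if j < len(plant_pool):
            category = plant_pool[j]
        r = rng.random()
        groups = (
            frozenset({"approved"})
            if r < 0.85
            else frozenset({"experimental"})
            if r < 0.95
            else frozenset({"withdrawn"})
        )
        synonyms = []
        if j % 3 == 0:
            salt = DEFAULT_SALT_SUFFIXES[j % len(DEFAULT_SALT_SUFFIXES)].capitalize()
            synonyms.append(f"Drug{num:03d} {salt}")
        external_links = []
        if did in stage1_ids:
            external_links.append(("PharmGKB", f"PA9{num:04d}"))
        records.append(
            DrugRecord(
                drugbank_id=did,
                name=name,
                synonyms=synonyms,
                groups=groups,
                categories=[category],
                indication=rng.choice(_INDICATIONS),
                atc_codes=[code],
                ddi_partners=[],
                target_acs=[ac_of[s] for s in rng.sample(symbols, rng.randint(1, 3))],
                external_links=external_links,
            )
        )

    # Extras: ambiguous-name pairs, one drug with a dangling DDI partner.
    for i in range(p.n_ambiguous_links):
        shared = _AMBIGUOUS_SYNONYMS[i]
        for half, did in enumerate(extra_ids[2 * i : 2 * i + 2]):
            num = int(did[2:])
            records.append(
                DrugRecord(
                    drugbank_id=did,
                    name=f"drug{num:03d}",
                    synonyms=[shared],
                    groups=frozenset({"experimental"}),
                    categories=["miscellaneous"],
                    indication=rng.choice(_INDICATIONS),
                )
            )
    for did in extra_ids[2 * p.n_ambiguous_links :]:
        num = int(did[2:])
        records.append(
            DrugRecord(
                drugbank_id=did,
                name=f"drug{num:03d}",
                synonyms=[],
                groups=frozenset({"approved"}),
                categories=["miscellaneous"],
                indication=rng.choice(_INDICATIONS),
                ddi_partners=[("DB99999", "Interaction with an unregistered drug.")],
            )
        )
    n_dangling = 1 if extra_ids[2 * p.n_ambiguous_links :] else 0

    # ---- associations ---------------------------------------------------
    assoc_rows: list[tuple[str, str, str, str]] = []
    for sym in assoc_syms:
        evidence = "PK/PD" if sym in set(overlap_syms) else rng.choice(["PK", "PD", "PK/PD"])
        assoc_rows.append(("PA90001", "drug001", sym, evidence))
    for did in stage1_ids:
        num = int(did[2:])
        for sym in rng.sample(symbols, 2):
            assoc_rows.append((f"PA9{num:04d}", f"drug{num:03d}", sym, rng.choice(["PK", "PD"])))
    for i, did in enumerate(stage2_ids):
        num = int(did[2:])
        # case-varied name or salt-suffixed synonym: both normalise to the drug name
        rec = next(r for r in records if r.drugbank_id == did)
        dname = rec.synonyms[0] if rec.synonyms else f"Drug{num:03d}"
        for sym in rng.sample(symbols, 2):
            assoc_rows.append((f"PA8{num:04d}", dname, sym, rng.choice(["PK", "PD"])))
    for i in range(p.n_ambiguous_links):
        assoc_rows.append(
            (f"PA7{i + 1:04d}", _AMBIGUOUS_SYNONYMS[i], rng.choice(symbols), "PD")
        )
    n_assoc_valid = len(assoc_rows)
    for i in range(p.n_invalid_assoc):
        assoc_rows.append((f"PA6{i + 1:04d}", f"badrug{i}", rng.choice(symbols), "PX"))

    # ---- MITAB ----------------------------------------------------------
    lines: list[str] = []
    for idx, (a, b) in enumerate(graph.edges):
        lines.append(
            _mitab_line(
                ac_of[a],
                ac_of[b],
                _EXPERIMENTAL_METHODS[idx % len(_EXPERIMENTAL_METHODS)],
                _HUMAN,
                _HUMAN,
                _SOURCE_DBS[idx % len(_SOURCE_DBS)],
            )
        )
    for idx, (a, b) in enumerate(graph.edges[: p.planted_duplicates]):
        lines.append(
            _mitab_line(
                ac_of[b],
                ac_of[a],
                _EXPERIMENTAL_METHODS[(idx + 1) % len(_EXPERIMENTAL_METHODS)],
                _HUMAN,
                _HUMAN,
                _SOURCE_DBS[(idx + 1) % len(_SOURCE_DBS)],
            )
        )
    for _ in range(p.planted_self_loops):
        s = rng.choice(symbols)
        lines.append(_mitab_line(ac_of[s], ac_of[s], _EXPERIMENTAL_METHODS[0], _HUMAN, _HUMAN, _SOURCE_DBS[0]))
    for _ in range(p.planted_nonhuman):
        a, b = rng.sample(symbols, 2)
        lines.append(_mitab_line(ac_of[a], ac_of[b], _EXPERIMENTAL_METHODS[1], _HUMAN, _MOUSE, _SOURCE_DBS[1]))
    planted_pred = 0
    while planted_pred < p.planted_predicted_only:
        a, b = rng.sample(symbols, 2)
        if tuple(sorted((a, b))) in edge_set:
            continue
        lines.append(_mitab_line(ac_of[a], ac_of[b], _PREDICTED_METHOD, _HUMAN, _HUMAN, _SOURCE_DBS[2]))
        planted_pred += 1
    for i in range(p.planted_unmapped):
        ha = hole_acs[i % len(hole_acs)] if hole_acs else f"Q{30001 + i}"
        s = rng.choice(symbols)
        lines.append(_mitab_line(ha, ac_of[s], _EXPERIMENTAL_METHODS[2], _HUMAN, _HUMAN, _SOURCE_DBS[3]))
    rng.shuffle(lines)
    raw_rows = len(lines)

    # ---- gene sets ------------------------------------------------------
    network_genes = sorted(set(target_syms) | set(assoc_syms))
    planted_members = set(rng.sample(network_genes, p.planted_enriched_set_overlap))
    filler_pool = [s for s in symbols if s not in planted_members]
    planted_members |= set(rng.sample(filler_pool, p.gene_set_size - len(planted_members)))
    gmt_rows = [("PATHWAY_PLANTED", "planted drug-response pathway", sorted(planted_members))]
    for i in range(p.gene_set_count - 1):
        members = sorted(rng.sample(symbols, p.gene_set_size))
        gmt_rows.append((f"PATHWAY{i + 1:03d}", f"random pathway {i + 1}", members))

    # ---- expected-network bookkeeping (naive scans) ---------------------
    seeds = set(network_genes)
    incident = [(a, b) for a, b in graph.edges if a in seeds or b in seeds]
    interactors = sorted({x for e in incident for x in e} - seeds)
    n_target_only = len(set(target_syms) - set(assoc_syms))
    n_assoc_only = len(set(assoc_syms) - set(target_syms))
    network_nodes = 1 + n_inter + len(seeds) + len(interactors)
    network_edges = n_inter + len(target_syms) + len(assoc_syms) + len(incident)

    # simplification: drop the 54 interacting drugs, then single-pass
    # removal of non-candidate nodes with degree <= 1
    post_drug_edges: list[tuple[str, str]] = []
    post_drug_edges += [(cand_id, t) for t in target_syms]
    post_drug_edges += [(cand_id, g) for g in assoc_syms]
    post_drug_edges += incident
    deg = Counter()
    for a, b in post_drug_edges:
        deg[a] += 1
        deg[b] += 1
    post_drug_nodes = {cand_id} | seeds | set(interactors)
    low = {n for n in post_drug_nodes if n != cand_id and deg[n] <= 1}
    surviving = post_drug_nodes - low
    surv_edges = [(a, b) for a, b in post_drug_edges if a in surviving and b in surviving]
    # connected components of the simplified graph
    adj = defaultdict(set)
    for a, b in surv_edges:
        adj[a].add(b)
        adj[b].add(a)
    unvisited = set(surviving)
    n_modules = 0
    while unvisited:
        n_modules += 1
        stack = [unvisited.pop()]
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb in unvisited:
                    unvisited.remove(nb)
                    stack.append(nb)

    # ATC bookkeeping over interacting drugs
    level1 = Counter(prefix[0] for prefix in atc_prefixes)
    category_counts = Counter()
    for r in records:
        if r.drugbank_id in set(inter_ids):
            for c in r.categories:
                category_counts[c] += 1

    # ---- write files ----------------------------------------------------
    paths = {
        "drug_xml": out / "drugs.xml",
        "associations": out / "associations.tsv",
        "ppi_mitab": out / "ppi.mitab",
        "idmap": out / "idmap.tsv",
        "atc_table": out / "atc_codes.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "manifest": out / "manifest.json",
        "config": out / "config.yaml",
    }
    write_drug_xml(records, paths["drug_xml"])
    write_associations(assoc_rows, paths["associations"])
    with open(paths["ppi_mitab"], "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    write_idmap(idmap_rows, paths["idmap"])
    atc_table_rows = [(r.drugbank_id, c) for r in records for c in r.atc_codes]
    write_atc_table(atc_table_rows, paths["atc_table"])
    with open(paths["gene_sets"], "w", encoding="utf-8") as fh:
        for name, desc, members in gmt_rows:
            fh.write("\t".join([name, desc, *members]) + "\n")

    manifest = {
        "params": asdict(p),
        "n_drugs": len(records),
        "candidate": {
            "drugbank_id": cand_id,
            "name": "drug001",
            "n_ddi": n_inter,
            "n_targets": len(target_syms),
            "n_assoc_genes": len(assoc_syms),
            "n_overlap": p.n_overlap,
            "target_symbols": target_syms,
            "assoc_symbols": assoc_syms,
            "overlap_symbols": overlap_syms,
        },
        "associations": {"n_valid": n_assoc_valid, "n_invalid": p.n_invalid_assoc},
        "idmap": {"n_rows": len(idmap_rows), "n_holes": n_holes},
        "ppi": {
            "raw_rows": raw_rows,
            "valid_edges": len(graph.edges),
            "excluded": {
                "self_interaction": p.planted_self_loops,
                "non_human": p.planted_nonhuman,
                "not_experimental": p.planted_predicted_only,
                "unmapped": p.planted_unmapped,
            },
            "duplicates_collapsed": p.planted_duplicates,
            "hub": graph.hub,
            "hub_degree": graph.degrees[graph.hub],
        },
        "link": {
            "stage1": p.n_stage1_links,
            "stage2": p.n_stage2_links,
            "ambiguous": p.n_ambiguous_links,
        },
        "dangling_ddi_partners": n_dangling,
        "category_counts": dict(sorted(category_counts.items())),
        "network": {
            "n_nodes": network_nodes,
            "n_edges": network_edges,
            "roles": {
                "candidate_drug": 1,
                "interacting_drug": n_inter,
                "target": n_target_only,
                "associated_gene": n_assoc_only,
                "target_and_gene": p.n_overlap,
                "interactor_protein": len(interactors),
            },
            "n_ppi_edges": len(incident),
        },
        "simplified": {
            "n_drugs_removed": n_inter,
            "n_low_degree_removed": len(low),
            "n_nodes": len(surviving),
            "n_edges": len(surv_edges),
            "n_modules": n_modules,
        },
        "atc": {
            "n_classified": n_inter,
            "level1": dict(sorted(level1.items())),
            "level3": dict(sorted(p.atc_composition.items())),
        },
        "enrichment": {
            "planted_set": "PATHWAY_PLANTED",
            "planted_overlap": p.planted_enriched_set_overlap,
            "n_sets": p.gene_set_count,
        },
    }
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    config_text = "\n".join(
        [
            f"drug_xml: {paths['drug_xml'].name}",
            f"associations: {paths['associations'].name}",
            f"ppi_mitab: {paths['ppi_mitab'].name}",
            f"idmap: {paths['idmap'].name}",
            f"atc_table: {paths['atc_table'].name}",
            f"gene_sets: {paths['gene_sets'].name}",
            "hub_fraction: 0.05",
            "alpha: 0.01",
            "atc_level: 3",
            "",
        ]
    )
    with open(paths["config"], "w", encoding="utf-8") as fh:
        fh.write(config_text)

    return {k: str(v) for k, v in paths.items()}, manifest
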