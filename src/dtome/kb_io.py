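"""Readers, writers and cross-linking for the drug/gene/protein knowledge sources.

The workflow integrates four kinds of evidence before any network is built:

* a drug knowledge file (DrugBank-style XML dialect) carrying adverse
  drug-drug interactions, primary targets as UniProtKB accessions, status
  groups, categories, indications and ATC codes;
* a pharmacogenomic drug-gene association table (PharmGKB style) with
  pharmacokinetic (PK) / pharmacodynamic (PD) evidence labels;
* a protein-protein interaction file in PSI-MI TAB 2.5, filtered down to
  human, experimentally supported, non-redundant, non-self interactions;
* an identifier map UniProtKB AC -> Entrez Gene ID -> gene symbol, used to
  express every protein as a gene symbol.

Everything a parser excludes is counted and reported; silent loss during
integration is the failure mode this module is designed against.
"""

from __future__ import annotations

import csv
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

#: The five drug approval-status tokens (case-normalised on ingest).
STATUS_GROUPS = frozenset(
    {"approved", "experimental", "nutraceutical", "illicit", "withdrawn"}
)

#: Evidence vocabulary for drug-gene associations.
EVIDENCE_TOKENS = frozenset({"PK", "PD"})

HUMAN_TAXON = 9606

#: Salt/ester suffixes stripped (one trailing token) when normalising drug names.
DEFAULT_SALT_SUFFIXES = (
    "hydrochloride",
    "hydrobromide",
    "sulfate",
    "sulphate",
    "sodium",
    "potassium",
    "calcium",
    "maleate",
    "mesylate",
    "tartrate",
    "citrate",
    "acetate",
    "phosphate",
    "succinate",
    "fumarate",
    "besylate",
    "nitrate",
)

#: PSI-MI detection-method identifiers treated as predicted/in-silico evidence.
DEFAULT_PREDICTED_METHOD_IDS = frozenset(
    {"MI:0063", "MI:0064", "MI:0085", "MI:0362", "MI:0363"}
)

#: Keyword fallbacks for method strings lacking an MI identifier.
DEFAULT_PREDICTED_KEYWORDS = ("predict", "in silico", "interolog", "inference")

_MI_ID_RE = re.compile(r"MI:\d{4}")
_TAXID_RE = re.compile(r"taxid:(-?\d+)")
_PAREN_RE = re.compile(r"\(([^)]+)\)")


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass
class DrugRecord:
    """One drug with its identifiers, vocabulary fields and relations."""

    drugbank_id: str
    name: str
    synonyms: list[str] = field(default_factory=list)
    groups: frozenset[str] = frozenset()
    categories: list[str] = field(default_factory=list)
    indication: str = ""
    atc_codes: list[str] = field(default_factory=list)
    ddi_partners: list[tuple[str, str]] = field(default_factory=list)
    target_acs: list[str] = field(default_factory=list)
    external_links: list[tuple[str, str]] = field(default_factory=list)


@dataclass(frozen=True)
class DrugGeneAssociation:
    """A drug <-> gene link with PK/PD evidence from the pharmacogenomic source."""

    source_drug_id: str
    drug_name: str
    gene_symbol: str
    evidence: frozenset[str]


@dataclass(frozen=True)
class PPIEdge:
    """A canonical undirected human protein-protein interaction.

    ``symbol_a < symbol_b`` lexicographically; sources record the databases
    contributing evidence for the (possibly merged) pair.
    """

    symbol_a: str
    symbol_b: str
    sources: tuple[str, ...] = ()
    evidence_kind: str = "experimental"

    def __post_init__(self):
        if self.symbol_a >= self.symbol_b:
            raise ValidationError(
                f"PPIEdge endpoints must be canonically ordered and distinct: "
                f"{self.symbol_a!r} vs {self.symbol_b!r}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.symbol_a, self.symbol_b)


def make_ppi_edge(a: str, b: str, sources=(), evidence_kind="experimental") -> PPIEdge:
    """Build a canonically ordered edge from an unordered symbol pair."""
    if a == b:
        raise ValidationError(f"self-interaction {a!r} cannot form a PPIEdge")
    lo, hi = sorted((a, b))
    return PPIEdge(lo, hi, tuple(sources), evidence_kind)


@dataclass
class IdMap:
    """Two-step identifier map: UniProtKB AC -> Entrez Gene ID -> gene symbol."""

    ac_to_geneid: dict[str, str] = field(default_factory=dict)
    geneid_to_symbol: dict[str, str] = field(default_factory=dict)

    def symbol_for(self, ac: str) -> str | None:
        gid = self.ac_to_geneid.get(ac)
        if gid is None:
            return None
        return self.geneid_to_symbol.get(gid)

    @classmethod
    def identity(cls, symbols) -> "IdMap":
        """A map sending each symbol to itself (useful for symbol-keyed inputs)."""
        m = {s: s for s in symbols}
        return cls(dict(m), dict(m))


@dataclass(frozen=True)
class RawInteraction:
    """One PSI-MI TAB row reduced to the fields the filter needs."""

    id_a: str
    id_b: str
    detection_method: str
    taxon_a: int | None
    taxon_b: int | None
    source_db: str
    line: int = 0


@dataclass
class MitabResult:
    rows: list[RawInteraction]
    report: dict


@dataclass
class PPIFilterResult:
    edges: list[PPIEdge]
    report: dict
    #: raw rows that survived every exclusion rule (before de-duplication);
    #: re-filtering exactly these rows reproduces ``edges``.
    kept_rows: list[RawInteraction] = field(default_factory=list)


@dataclass
class AssociationResult:
    associations: list[DrugGeneAssociation]
    report: list[dict]


@dataclass
class DrugLink:
    """Bidirectional link between drug-knowledge ids and pharmacogenomic ids."""

    db_to_src: dict[str, str]
    src_to_db: dict[str, str]
    stage1: frozenset[str]
    stage2: frozenset[str]
    ambiguous: list[dict]

    def report(self) -> dict:
        return {
            "n_linked": len(self.db_to_src),
            "n_stage1": len(self.stage1),
            "n_stage2": len(self.stage2),
            "n_ambiguous": len(self.ambiguous),
            "ambiguous": self.ambiguous,
        }


# ---------------------------------------------------------------------------
# Drug XML
# ---------------------------------------------------------------------------

_KNOWN_DRUG_CHILDREN = {
    "name",
    "synonyms",
    "groups",
    "categories",
    "indication",
    "atc-codes",
    "drug-interactions",
    "targets",
    "external-links",
}


def parse_drug_xml(path) -> list[DrugRecord]:
    """Parse the documented drug XML dialect into :class:`DrugRecord` objects.

    Unknown elements are skipped with a log entry; unknown status-group
    tokens and duplicate drug ids are hard validation errors.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"drug XML not found: {path}")
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        line, col = exc.position
        raise InputError(f"malformed XML in {path} at line {line}: {exc}") from exc

    root = tree.getroot()
    records: list[DrugRecord] = []
    seen: set[str] = set()
    for el in root.findall("drug"):
        did = (el.get("id") or "").strip()
        if not did:
            raise ValidationError("drug element without an id attribute")
        if did in seen:
            raise ValidationError(f"duplicate drugbank_id: {did}")
        seen.add(did)

        for child in el:
            if child.tag not in _KNOWN_DRUG_CHILDREN:
                logger.info("drug %s: skipping unknown element <%s>", did, child.tag)

        groups = set()
        for g in el.findall("groups/group"):
            token = (g.text or "").strip().lower()
            if token not in STATUS_GROUPS:
                raise ValidationError(
                    f"unknown status group {token!r} for drug {did}; "
                    f"allowed: {sorted(STATUS_GROUPS)}"
                )
            groups.add(token)

        ddi: list[tuple[str, str]] = []
        for inter in el.findall("drug-interactions/interaction"):
            pid = (inter.findtext("partner-id") or "").strip()
            desc = (inter.findtext("description") or "").strip()
            if pid == did:
                raise ValidationError(f"drug {did} lists itself as an interaction partner")
            ddi.append((pid, desc))

        records.append(
            DrugRecord(
                drugbank_id=did,
                name=(el.findtext("name") or "").strip(),
                synonyms=[(s.text or "").strip() for s in el.findall("synonyms/synonym")],
                groups=frozenset(groups),
                categories=[(c.text or "").strip() for c in el.findall("categories/category")],
                indication=(el.findtext("indication") or "").strip(),
                atc_codes=[(a.text or "").strip() for a in el.findall("atc-codes/atc-code")],
                ddi_partners=ddi,
                target_acs=[t.get("ac") for t in el.findall("targets/target") if t.get("ac")],
                external_links=[
                    (ln.get("source") or "", ln.get("id") or "")
                    for ln in el.findall("external-links/link")
                ],
            )
        )
    return records


def write_drug_xml(records, path) -> None:
    """Serialise drug records back into the XML dialect (round-trip safe)."""
    root = ET.Element("drugs")
    for r in records:
        d = ET.SubElement(root, "drug", id=r.drugbank_id)
        ET.SubElement(d, "name").text = r.name
        syn = ET.SubElement(d, "synonyms")
        for s in r.synonyms:
            ET.SubElement(syn, "synonym").text = s
        grp = ET.SubElement(d, "groups")
        for g in sorted(r.groups):
            ET.SubElement(grp, "group").text = g
        cat = ET.SubElement(d, "categories")
        for c in r.categories:
            ET.SubElement(cat, "category").text = c
        ET.SubElement(d, "indication").text = r.indication
        atc = ET.SubElement(d, "atc-codes")
        for a in r.atc_codes:
            ET.SubElement(atc, "atc-code").text = a
        ddis = ET.SubElement(d, "drug-interactions")
        for pid, desc in r.ddi_partners:
            inter = ET.SubElement(ddis, "interaction")
            ET.SubElement(inter, "partner-id").text = pid
            ET.SubElement(inter, "description").text = desc
        tg = ET.SubElement(d, "targets")
        for ac in r.target_acs:
            ET.SubElement(tg, "target", ac=ac)
        xl = ET.SubElement(d, "external-links")
        for source, fid in r.external_links:
            ET.SubElement(xl, "link", source=source, id=fid)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)


# ---------------------------------------------------------------------------
# PSI-MI TAB
# ---------------------------------------------------------------------------

def _strip_db_prefix(token: str) -> str:
    return token.split(":", 1)[1] if ":" in token else token


def _parse_taxon(token: str) -> int | None:
    m = _TAXID_RE.search(token)
    return int(m.group(1)) if m else None


def parse_ppi_mitab(path) -> MitabResult:
    """Read a PSI-MI TAB 2.5 file into raw interaction rows.

    Rows with fewer than 15 tab-separated columns are skipped and recorded
    in the report; parsing continues. Column usage: 1-2 interactor ids,
    7 detection method, 10-11 taxa, 13 source database.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"PSI-MI TAB file not found: {path}")
    rows: list[RawInteraction] = []
    errors: list[dict] = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 15:
                errors.append({"line": ln, "reason": f"{len(cols)} columns (expected >= 15)"})
                continue
            rows.append(
                RawInteraction(
                    id_a=_strip_db_prefix(cols[0]),
                    id_b=_strip_db_prefix(cols[1]),
                    detection_method=cols[6],
                    taxon_a=_parse_taxon(cols[9]),
                    taxon_b=_parse_taxon(cols[10]),
                    source_db=cols[12],
                    line=ln,
                )
            )
    if not rows:
        logger.warning("no interaction rows parsed from %s", path)
    return MitabResult(rows=rows, report={"n_rows": len(rows), "errors": errors})


def is_experimental_method(
    method: str,
    allow=None,
    deny_ids=DEFAULT_PREDICTED_METHOD_IDS,
    deny_keywords=DEFAULT_PREDICTED_KEYWORDS,
) -> bool:
    """Decide whether a PSI-MI detection-method string counts as experimental.

    With an explicit ``allow`` list only listed MI ids / keywords pass;
    otherwise anything not matching the predicted/in-silico deny list passes.
    """
    mi = _MI_ID_RE.search(method)
    mi_id = mi.group(0) if mi else None
    low = method.lower()
    if allow is not None:
        return any(term == mi_id or term.lower() in low for term in allow)
    if mi_id is not None and mi_id in deny_ids:
        return False
    return not any(k in low for k in deny_keywords)


def _source_name(token: str) -> str:
    m = _PAREN_RE.search(token)
    return m.group(1) if m else token


def filter_ppi(
    rows,
    idmap: IdMap,
    taxon: int = HUMAN_TAXON,
    allow=None,
    deny_ids=DEFAULT_PREDICTED_METHOD_IDS,
    deny_keywords=DEFAULT_PREDICTED_KEYWORDS,
) -> PPIFilterResult:
    """Filter raw interaction rows into a clean human PPI edge set.

    Exclusion rules, applied in order and counted per reason:
    non-human taxa, non-experimental detection method, unmapped interactor,
    self-interaction. Surviving unordered duplicates collapse into one edge
    with the union of source databases.
    """
    reasons = {
        "non_human": 0,
        "not_experimental": 0,
        "unmapped": 0,
        "self_interaction": 0,
    }
    merged: dict[tuple[str, str], set[str]] = {}
    kept: list[RawInteraction] = []
    duplicates = 0
    for r in rows:
        if r.taxon_a != taxon or r.taxon_b != taxon:
            reasons["non_human"] += 1
            continue
        if not is_experimental_method(r.detection_method, allow, deny_ids, deny_keywords):
            reasons["not_experimental"] += 1
            continue
        sa = idmap.symbol_for(r.id_a)
        sb = idmap.symbol_for(r.id_b)
        if sa is None or sb is None:
            reasons["unmapped"] += 1
            continue
        if sa == sb:
            reasons["self_interaction"] += 1
            continue
        kept.append(r)
        key = (min(sa, sb), max(sa, sb))
        src = _source_name(r.source_db)
        if key in merged:
            duplicates += 1
            merged[key].add(src)
        else:
            merged[key] = {src}
    edges = [
        PPIEdge(a, b, tuple(sorted(srcs)), "experimental")
        for (a, b), srcs in sorted(merged.items())
    ]
    report = {
        "raw_rows": len(rows),
        "valid_edges": len(edges),
        "excluded": reasons,
        "duplicates_collapsed": duplicates,
    }
    return PPIFilterResult(edges=edges, report=report, kept_rows=kept)


# ---------------------------------------------------------------------------
# Drug-gene associations
# ---------------------------------------------------------------------------

_ASSOC_COLUMNS = ("drug_id", "drug_name", "gene_symbol", "evidence")


def parse_drug_gene_associations(path) -> AssociationResult:
    """Read the drug-gene association TSV; reject rows with unknown evidence.

    Evidence strings are split on ``/`` into the {PK, PD} subset; gene
    symbols are upper-cased on ingest.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"association table not found: {path}")
    associations: list[DrugGeneAssociation] = []
    report: list[dict] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise InputError(f"association table {path} is empty") from None
        if tuple(h.strip() for h in header) != _ASSOC_COLUMNS:
            raise InputError(
                f"association table {path} must have header {list(_ASSOC_COLUMNS)}, "
                f"got {header}"
            )
        for ln, row in enumerate(reader, 2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 4:
                report.append({"line": ln, "reason": "too few columns"})
                continue
            drug_id, drug_name, gene, evidence_raw = (c.strip() for c in row[:4])
            tokens = [t.strip().upper() for t in evidence_raw.split("/") if t.strip()]
            bad = [t for t in tokens if t not in EVIDENCE_TOKENS]
            if bad or not tokens:
                report.append(
                    {"line": ln, "reason": "unknown evidence token", "tokens": bad or [evidence_raw]}
                )
                continue
            associations.append(
                DrugGeneAssociation(
                    source_drug_id=drug_id,
                    drug_name=drug_name,
                    gene_symbol=gene.upper(),
                    evidence=frozenset(tokens),
                )
            )
    return AssociationResult(associations=associations, report=report)


def write_associations(rows, path) -> None:
    """Write (drug_id, drug_name, gene_symbol, evidence) rows as TSV."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(_ASSOC_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


# ---------------------------------------------------------------------------
# Identifier mapping
# ---------------------------------------------------------------------------

def load_idmap(path) -> IdMap:
    """Load the AC -> Gene ID -> symbol TSV. Empty fields leave mapping holes."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"idmap table not found: {path}")
    idmap = IdMap()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["ac", "gene_id", "symbol"]:
            raise InputError(f"idmap table {path} must have header ac/gene_id/symbol")
        for row in reader:
            if not row or not row[0].strip():
                continue
            ac = row[0].strip()
            gid = row[1].strip() if len(row) > 1 else ""
            sym = row[2].strip().upper() if len(row) > 2 else ""
            if gid:
                idmap.ac_to_geneid[ac] = gid
                if sym:
                    idmap.geneid_to_symbol[gid] = sym
    return idmap


def write_idmap(rows, path) -> None:
    """Write (ac, gene_id, symbol) rows as TSV; empty strings encode holes."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("ac\tgene_id\tsymbol\n")
        for ac, gid, sym in rows:
            fh.write(f"{ac}\t{gid}\t{sym}\n")


def map_ac_to_symbol(acs, idmap: IdMap) -> tuple[dict[str, str], list[str]]:
    """Two-step AC -> symbol lookup; ACs failing either step are reported."""
    mapped: dict[str, str] = {}
    unmapped: list[str] = []
    seen: set[str] = set()
    for ac in acs:
        if ac in seen:
            continue
        seen.add(ac)
        sym = idmap.symbol_for(ac)
        if sym is None:
            unmapped.append(ac)
        else:
            mapped[ac] = sym
    return mapped, unmapped


# ---------------------------------------------------------------------------
# ATC table
# ---------------------------------------------------------------------------

def load_atc_table(path) -> dict[str, list[str]]:
    """Load a drug_id -> ATC code table (one code per row)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"ATC table not found: {path}")
    table: dict[str, list[str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["drug_id", "atc_code"]:
            raise InputError(f"ATC table {path} must have header drug_id/atc_code")
        for row in reader:
            if len(row) < 2 or not row[0].strip():
                continue
            table.setdefault(row[0].strip(), []).append(row[1].strip())
    return table


def write_atc_table(rows, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("drug_id\tatc_code\n")
        for did, code in rows:
            fh.write(f"{did}\t{code}\n")


# ---------------------------------------------------------------------------
# Drug name normalisation and vocabulary linking
# ---------------------------------------------------------------------------

def normalize_drug_name(name: str, salt_suffixes=DEFAULT_SALT_SUFFIXES) -> str:
    """Canonicalise a drug name for cross-source matching.

    Lower-case, strip and collapse whitespace, and drop one trailing
    salt/ester token from the configured suffix list.
    """
    if name is None or not name.strip():
        raise ValidationError("drug name is empty")
    tokens = name.lower().split()
    suffixes = {s.lower() for s in salt_suffixes}
    if len(tokens) > 1 and tokens[-1] in suffixes:
        tokens = tokens[:-1]
    return " ".join(tokens)


_PHARMACO_SOURCES = {"pharmgkb"}


def link_drug_vocabularies(
    drugs,
    associations,
    salt_suffixes=DEFAULT_SALT_SUFFIXES,
) -> DrugLink:
    """Link drug-knowledge ids to pharmacogenomic source ids in two stages.

    Stage 1 uses explicit external-link foreign ids; stage 2 matches the
    remaining drugs by normalised name/synonym equality. Stage-1 links are
    never overwritten; ambiguous stage-2 matches are reported, not linked.
    """
    db_to_src: dict[str, str] = {}
    src_to_db: dict[str, str] = {}
    stage1: set[str] = set()
    stage2: set[str] = set()
    ambiguous: list[dict] = []

    for drug in drugs:
        fids = sorted(
            {fid for (source, fid) in drug.external_links if source.lower() in _PHARMACO_SOURCES and fid}
        )
        if len(fids) > 1:
            raise ValidationError(
                f"drug {drug.drugbank_id} has conflicting pharmacogenomic links: {fids}"
            )
        if fids:
            fid = fids[0]
            if fid in src_to_db and src_to_db[fid] != drug.drugbank_id:
                raise ValidationError(
                    f"source id {fid} explicitly linked to both "
                    f"{src_to_db[fid]} and {drug.drugbank_id}"
                )
            db_to_src[drug.drugbank_id] = fid
            src_to_db[fid] = drug.drugbank_id
            stage1.add(drug.drugbank_id)

    # Stage 2: name-based matching over drugs without an explicit link.
    name_index: dict[str, set[str]] = {}
    for drug in drugs:
        if drug.drugbank_id in db_to_src:
            continue
        for candidate_name in [drug.name, *drug.synonyms]:
            if not candidate_name or not candidate_name.strip():
                continue
            norm = normalize_drug_name(candidate_name, salt_suffixes)
            name_index.setdefault(norm, set()).add(drug.drugbank_id)

    pending: dict[str, str] = {}
    for assoc in associations:
        if assoc.source_drug_id not in src_to_db and assoc.source_drug_id not in pending:
            pending[assoc.source_drug_id] = assoc.drug_name

    for sid in sorted(pending):
        dname = pending[sid]
        if not dname or not dname.strip():
            continue
        norm = normalize_drug_name(dname, salt_suffixes)
        hits = name_index.get(norm)
        if not hits:
            continue
        if len(hits) > 1:
            ambiguous.append(
                {"source_drug_id": sid, "drug_name": dname, "candidates": sorted(hits)}
            )
            continue
        (db_id,) = hits
        if db_id in db_to_src:
            ambiguous.append(
                {
                    "source_drug_id": sid,
                    "drug_name": dname,
                    "candidates": [db_id],
                    "reason": "drug already linked to another source id",
                }
            )
            continue
        db_to_src[db_id] = sid
        src_to_db[sid] = db_id
        stage2.add(db_id)

    return DrugLink(
        db_to_src=db_to_src,
        src_to_db=src_to_db,
        stage1=frozenset(stage1),
        stage2=frozenset(stage2),
        ambiguous=ambiguous,
    )


# ---------------------------------------------------------------------------
# Knowledge base
# ---------------------------------------------------------------------------

@dataclass
class KnowledgeBase:
    """All cross-linked sources behind one queryable object."""

    drugs: dict[str, DrugRecord]
    associations: list[DrugGeneAssociation]
    ppi: list[PPIEdge]
    idmap: IdMap
    drug_link: DrugLink
    reports: dict = field(default_factory=dict)

    def get_drug(self, drug_id: str) -> DrugRecord:
        try:
            return self.drugs[drug_id]
        except KeyError:
            raise ValidationError(f"unknown drug id: {drug_id}") from None

    @classmethod
    def load(
        cls,
        drug_xml,
        associations_tsv,
        ppi_mitab,
        idmap_tsv,
        taxon: int = HUMAN_TAXON,
        experimental_allow=None,
        predicted_deny_ids=DEFAULT_PREDICTED_METHOD_IDS,
        salt_suffixes=DEFAULT_SALT_SUFFIXES,
    ) -> "KnowledgeBase":
        records = parse_drug_xml(drug_xml)
        drugs = {r.drugbank_id: r for r in records}
        idmap = load_idmap(idmap_tsv)
        assoc = parse_drug_gene_associations(associations_tsv)
        mitab = parse_ppi_mitab(ppi_mitab)
        filt = filter_ppi(
            mitab.rows,
            idmap,
            taxon=taxon,
            allow=experimental_allow,
            deny_ids=predicted_deny_ids,
        )
        link = link_drug_vocabularies(records, assoc.associations, salt_suffixes)

        dangling = sorted(
            {pid for r in records for pid, _ in r.ddi_partners if pid not in drugs}
        )
        unmapped_targets = {}
        for r in records:
            _, unmapped = map_ac_to_symbol(r.target_acs, idmap)
            if unmapped:
                unmapped_targets[r.drugbank_id] = unmapped

        reports = {
            "mitab": mitab.report,
            "ppi_filter": filt.report,
            "associations": {"n_valid": len(assoc.associations), "rejected": assoc.report},
            "link": link.report(),
            "dangling_ddi_partners": dangling,
            "unmapped_target_acs": unmapped_targets,
        }
        return cls(
            drugs=drugs,
            associations=assoc.associations,
            ppi=filt.edges,
            idmap=idmap,
            drug_link=link,
            reports=reports,
        )
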