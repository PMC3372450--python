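"""Knowledge-source parsing, PPI filtering, id mapping and vocabulary linking."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtome import (
    DrugGeneAssociation,
    DrugRecord,
    IdMap,
    InputError,
    ValidationError,
    filter_ppi,
    link_drug_vocabularies,
    map_ac_to_symbol,
    normalize_drug_name,
    parse_drug_gene_associations,
    parse_drug_xml,
    parse_ppi_mitab,
)
from dtome.kb_io import RawInteraction, write_drug_xml

DRUG_XML = """<?xml version="1.0" encoding="utf-8"?>
<drugs>
  <drug id="DB00001">
    <name>Alphadrug</name>
    <synonyms><synonym>Alphadrug Hydrochloride</synonym></synonyms>
    <groups><group>Approved</group><group>withdrawn</group></groups>
    <categories><category>antipsychotic</category></categories>
    <indication>schizophrenia</indication>
    <atc-codes><atc-code>N05AH02</atc-code></atc-codes>
    <drug-interactions>
      <interaction><partner-id>DB00002</partner-id><description>risk up</description></interaction>
      <interaction><partner-id>DB00003</partner-id><description>risk down</description></interaction>
    </drug-interactions>
    <targets><target ac="P10001"/></targets>
    <external-links><link source="PharmGKB" id="PA123"/></external-links>
    <mystery-element>ignored</mystery-element>
  </drug>
  <drug id="DB00002"><name>Betadrug</name></drug>
  <drug id="DB00003"><name>Gammadrug</name></drug>
</drugs>
"""


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestDrugXml:
    def test_element_counts_and_fields(self, tmp_path):
        records = parse_drug_xml(_write(tmp_path, "d.xml", DRUG_XML))
        assert len(records) == 3
        first = records[0]
        assert len(first.ddi_partners) == 2
        assert first.ddi_partners[0] == ("DB00002", "risk up")
        assert first.target_acs == ["P10001"]
        assert first.external_links == [("PharmGKB", "PA123")]
        assert first.atc_codes == ["N05AH02"]

    def test_group_tokens_case_normalized(self, tmp_path):
        records = parse_drug_xml(_write(tmp_path, "d.xml", DRUG_XML))
        assert records[0].groups == frozenset({"approved", "withdrawn"})

    @pytest.mark.parametrize(
        "mutation, exc, fragment",
        [
            ("</drugs>", InputError, "line"),  # truncation -> malformed XML
            ('id="DB00002"><name>Betadrug', ValidationError, "duplicate"),
            ("<group>Approved</group>", ValidationError, "bogus"),
        ],
    )
    def test_error_contracts(self, tmp_path, mutation, exc, fragment):
        if mutation == "</drugs>":
            text = DRUG_XML.replace("</drugs>", "")
        elif "duplicate" == fragment:
            text = DRUG_XML.replace('id="DB00003"', 'id="DB00002"')
        else:
            text = DRUG_XML.replace("<group>Approved</group>", "<group>bogus</group>")
        with pytest.raises(exc, match=fragment):
            parse_drug_xml(_write(tmp_path, "bad.xml", text))

    def test_synth_manifest_drug_count(self, kb, manifest):
        assert len(kb.drugs) == manifest["n_drugs"]

    def test_round_trip_is_identity(self, tmp_path, kb_paths):
        records = parse_drug_xml(kb_paths["drug_xml"])
        out = tmp_path / "rt.xml"
        write_drug_xml(records, out)
        assert parse_drug_xml(out) == records


MITAB_ROW = (
    "uniprotkb:{a}\tuniprotkb:{b}\t-\t-\t-\t-\t{method}\t-\tpubmed:1\t"
    "taxid:{ta}(x)\ttaxid:{tb}(y)\t-\t{src}\t-\t-"
)


def _mitab(tmp_path, rows, name="ppi.mitab"):
    return _write(tmp_path, name, "\n".join(rows) + "\n")


def _row(a, b, method='psi-mi:"MI:0018"(two hybrid)', ta=9606, tb=9606, src="intact"):
    return MITAB_ROW.format(a=a, b=b, method=method, ta=ta, tb=tb, src=src)


class TestMitab:
    def test_rows_and_taxa_extracted(self, tmp_path):
        res = parse_ppi_mitab(
            _mitab(tmp_path, [_row("P1", "P2"), _row("P1", "P3"), _row("P2", "P3", ta=9606, tb=10090), _row("P4", "P5")])
        )
        assert len(res.rows) == 4
        assert (res.rows[2].taxon_a, res.rows[2].taxon_b) == (9606, 10090)

    def test_short_row_skipped_with_report(self, tmp_path):
        res = parse_ppi_mitab(_mitab(tmp_path, [_row("P1", "P2"), "only\tthree\tcolumns"]))
        assert len(res.rows) == 1
        assert res.report["errors"][0]["line"] == 2

    def test_empty_file_yields_empty_list(self, tmp_path):
        res = parse_ppi_mitab(_write(tmp_path, "e.mitab", ""))
        assert res.rows == [] and res.report["n_rows"] == 0

    def test_synth_manifest_row_count(self, kb_paths, manifest):
        res = parse_ppi_mitab(kb_paths["ppi_mitab"])
        assert len(res.rows) == manifest["ppi"]["raw_rows"]


def _identity_idmap(symbols):
    return IdMap.identity(symbols)


class TestFilterPPI:
    idmap = IdMap({"A": "1", "B": "2", "C": "3"}, {"1": "A", "2": "B", "3": "C"})

    def _rows(self, specs):
        return [
            RawInteraction(a, b, m, ta, tb, src)
            for a, b, m, ta, tb, src in specs
        ]

    def test_self_interactions_removed(self):
        rows = self._rows([("A", "A", 'psi-mi:"MI:0018"(two hybrid)', 9606, 9606, "intact")])
        res = filter_ppi(rows, self.idmap)
        assert res.edges == [] and res.report["excluded"]["self_interaction"] == 1

    def test_unordered_duplicates_collapse_with_merged_sources(self):
        rows = self._rows(
            [
                ("A", "B", 'psi-mi:"MI:0018"(two hybrid)', 9606, 9606, "x(intact)"),
                ("B", "A", 'psi-mi:"MI:0096"(pull down)', 9606, 9606, "x(mint)"),
            ]
        )
        res = filter_ppi(rows, self.idmap)
        assert len(res.edges) == 1
        assert res.edges[0].pair == ("A", "B")
        assert res.edges[0].sources == ("intact", "mint")
        assert res.report["duplicates_collapsed"] == 1

    def test_exclusion_rules_by_reason(self):
        rows = self._rows(
            [
                ("A", "B", 'psi-mi:"MI:0018"(two hybrid)', 9606, 10090, "intact"),
                ("A", "C", 'psi-mi:"MI:0063"(interaction prediction)', 9606, 9606, "intact"),
                ("A", "ZZZ", 'psi-mi:"MI:0018"(two hybrid)', 9606, 9606, "intact"),
                ("B", "C", 'psi-mi:"MI:0018"(two hybrid)', 9606, 9606, "intact"),
            ]
        )
        res = filter_ppi(rows, self.idmap)
        assert res.report["excluded"] == {
            "non_human": 1,
            "not_experimental": 1,
            "unmapped": 1,
            "self_interaction": 0,
        }
        assert [e.pair for e in res.edges] == [("B", "C")]

    def test_accounting_identity_and_idempotence(self, kb_paths, manifest):
        idmap_rows = parse_ppi_mitab(kb_paths["ppi_mitab"]).rows
        from dtome.kb_io import load_idmap

        idmap = load_idmap(kb_paths["idmap"])
        res = filter_ppi(idmap_rows, idmap)
        rep = res.report
        assert rep["raw_rows"] == (
            rep["valid_edges"]
            + sum(rep["excluded"].values())
            + rep["duplicates_collapsed"]
        )
        assert rep["excluded"] == manifest["ppi"]["excluded"]
        assert rep["valid_edges"] == manifest["ppi"]["valid_edges"]
        assert rep["duplicates_collapsed"] == manifest["ppi"]["duplicates_collapsed"]
        # idempotence: re-filtering the surviving rows reproduces the edges
        again = filter_ppi(res.kept_rows, idmap)
        assert again.edges == res.edges
        assert sum(again.report["excluded"].values()) == 0

    def test_filtered_set_invariants(self, kb, kb_paths):
        from dtome.kb_io import load_idmap

        idmap = load_idmap(kb_paths["idmap"])
        image = set(idmap.geneid_to_symbol.values())
        pairs = set()
        for e in kb.ppi:
            assert e.symbol_a < e.symbol_b
            assert e.symbol_a in image and e.symbol_b in image
            assert e.pair not in pairs
            pairs.add(e.pair)


ASSOC_TSV = "drug_id\tdrug_name\tgene_symbol\tevidence\n"


class TestAssociations:
    def test_field_parsing_and_case(self, tmp_path):
        res = parse_drug_gene_associations(
            _write(tmp_path, "a.tsv", ASSOC_TSV + "PA001\tclozapine\tdrd2\tPK/PD\n")
        )
        (assoc,) = res.associations
        assert assoc.gene_symbol == "DRD2"
        assert assoc.evidence == frozenset({"PK", "PD"})

    def test_unknown_evidence_rejected_with_token(self, tmp_path):
        res = parse_drug_gene_associations(
            _write(tmp_path, "a.tsv", ASSOC_TSV + "PA001\tx\tG1\tPX\n")
        )
        assert res.associations == []
        assert res.report[0]["tokens"] == ["PX"]

    def test_synth_manifest_counts(self, kb_paths, manifest):
        res = parse_drug_gene_associations(kb_paths["associations"])
        assert len(res.associations) == manifest["associations"]["n_valid"]
        assert len(res.report) == manifest["associations"]["n_invalid"]


class TestIdMapping:
    def test_two_step_composition(self):
        idmap = IdMap({"P1": "100"}, {"100": "GENEA"})
        assert map_ac_to_symbol(["P1"], idmap) == ({"P1": "GENEA"}, [])

    def test_missing_step_lands_in_unmapped(self):
        idmap = IdMap({"P2": "200"}, {})
        assert map_ac_to_symbol(["P2"], idmap) == ({}, ["P2"])
        assert map_ac_to_symbol(["P3"], IdMap()) == ({}, ["P3"])

    def test_synth_hole_count(self, kb_paths, manifest):
        from dtome.kb_io import load_idmap
        import csv

        idmap = load_idmap(kb_paths["idmap"])
        with open(kb_paths["idmap"], encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            next(reader)
            acs = [row[0] for row in reader if row]
        _, unmapped = map_ac_to_symbol(acs, idmap)
        assert len(acs) == manifest["idmap"]["n_rows"]
        assert len(unmapped) == manifest["idmap"]["n_holes"]


class TestNameNormalization:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("Clozapine ", "clozapine"),
            ("Fluoxetine  Hydrochloride", "fluoxetine"),
            ("ACETYL  SALICYLIC   acid", "acetyl salicylic acid"),
            ("Hydrochloride", "hydrochloride"),  # lone salt token is a name
        ],
    )
    def test_normalization_rules(self, raw, expected):
        assert normalize_drug_name(raw) == expected

    def test_empty_name_is_an_error(self):
        with pytest.raises(ValidationError):
            normalize_drug_name("   ")

    @given(
        st.text(
            alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Zs"), max_codepoint=0x2FF),
            min_size=1,
            max_size=40,
        ).filter(lambda s: s.strip())
    )
    @settings(derandomize=True, max_examples=80)
    def test_normalization_canonicalizes(self, name):
        # case/whitespace canonicalisation is idempotent; the salt strip is
        # a single pass by contract, so test it disabled here
        once = normalize_drug_name(name, salt_suffixes=())
        assert normalize_drug_name(once, salt_suffixes=()) == once
        assert once == once.lower() and "  " not in once and once == once.strip()
        # the default suffix list removes at most one trailing token
        stripped = normalize_drug_name(name)
        assert stripped == once or stripped == once.rsplit(" ", 1)[0]


def _assoc(sid, name, gene="G1"):
    return DrugGeneAssociation(sid, name, gene, frozenset({"PK"}))


class TestVocabularyLinking:
    def test_stage1_explicit_key(self):
        drug = DrugRecord("DB1", "Alphadrug", external_links=[("PharmGKB", "PA001")])
        link = link_drug_vocabularies([drug], [_assoc("PA001", "alphadrug")])
        assert link.db_to_src == {"DB1": "PA001"}
        assert link.stage1 == frozenset({"DB1"})

    def test_stage2_links_by_normalized_name(self):
        drug = DrugRecord("DB1", "Clozapine")
        link = link_drug_vocabularies([drug], [_assoc("PA001", "clozapine")])
        assert link.stage2 == frozenset({"DB1"})
        assert link.src_to_db == {"PA001": "DB1"}

    def test_stage2_synonym_with_salt_suffix(self):
        drug = DrugRecord("DB1", "Fluoxetine", synonyms=["Fluoxetine Hydrochloride"])
        link = link_drug_vocabularies([drug], [_assoc("PA9", "FLUOXETINE HYDROCHLORIDE")])
        assert link.db_to_src == {"DB1": "PA9"}

    def test_ambiguous_matches_reported_not_linked(self):
        drugs = [DrugRecord("DB1", "Twin"), DrugRecord("DB2", "twin")]
        link = link_drug_vocabularies(drugs, [_assoc("PA1", "Twin")])
        assert link.db_to_src == {}
        assert link.ambiguous[0]["candidates"] == ["DB1", "DB2"]

    def test_stage1_never_overwritten_by_stage2(self):
        drug = DrugRecord("DB1", "Solo", external_links=[("PharmGKB", "PA001")])
        link = link_drug_vocabularies(
            [drug], [_assoc("PA001", "whatever"), _assoc("PA777", "solo")]
        )
        assert link.db_to_src == {"DB1": "PA001"}
        assert "PA777" not in link.src_to_db

    def test_conflicting_explicit_links_error(self):
        drug = DrugRecord(
            "DB1", "X", external_links=[("PharmGKB", "PA1"), ("PharmGKB", "PA2")]
        )
        with pytest.raises(ValidationError, match="conflicting"):
            link_drug_vocabularies([drug], [])

    def test_synth_manifest_stage_counts(self, kb, manifest):
        link = kb.drug_link
        assert len(link.stage1) == manifest["link"]["stage1"]
        assert len(link.stage2) == manifest["link"]["stage2"]
        assert len(link.ambiguous) == manifest["link"]["ambiguous"]
        # stage totals are disjoint and links are injective both ways
        assert not (link.stage1 & link.stage2)
        assert len(set(link.db_to_src.values())) == len(link.db_to_src)
        assert len(set(link.src_to_db.values())) == len(link.src_to_db)
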