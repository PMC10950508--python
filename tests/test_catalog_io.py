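"""Catalog readers/writers: parsing rules, vocabularies, round trips."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxddi import catalog_io
from pgxddi.catalog_io import (
    CTET_ROLES,
    EVIDENCE_LEVELS,
    CatalogError,
    ClinicalAnnotation,
    DeleteriousnessAnnotation,
    DiplotypeCall,
    Drug,
    DrugGeneCatalog,
    Regimen,
    infer_allele_type,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestDrugList:
    def test_basic_parse_preserves_order_and_groups(self, tmp_path):
        p = _write(tmp_path, "drugs.tsv",
                   "name\tgroups\nwarfarin\tantithrombotic\nritonavir\tcause_treatment\n")
        drugs = catalog_io.read_drug_list(p)
        assert [d.name for d in drugs] == ["warfarin", "ritonavir"]
        assert drugs[0].groups == ("antithrombotic",)

    def test_header_only_gives_empty_list(self, tmp_path):
        p = _write(tmp_path, "drugs.tsv", "name\tgroups\n")
        assert catalog_io.read_drug_list(p) == []

    def test_unknown_group_names_offending_line(self, tmp_path):
        p = _write(tmp_path, "drugs.tsv",
                   "name\tgroups\nwarfarin\tantithrombotic\nx\tsteroid\n")
        with pytest.raises(CatalogError, match="line 3"):
            catalog_io.read_drug_list(p)

    def test_duplicate_name_rejected(self, tmp_path):
        p = _write(tmp_path, "drugs.tsv",
                   "name\tgroups\nwarfarin\tantithrombotic\nwarfarin\tcorticoid\n")
        with pytest.raises(CatalogError, match="duplicate"):
            catalog_io.read_drug_list(p)

    def test_multiple_group_tags(self, tmp_path):
        p = _write(tmp_path, "drugs.tsv",
                   "name\tgroups\naspirin\tantithrombotic;comorbidity_cvd\n")
        assert catalog_io.read_drug_list(p)[0].groups == ("antithrombotic", "comorbidity_cvd")


class TestAlleleTypeInference:
    @pytest.mark.parametrize("allele_id,expected", [
        ("rs9923231", "snp"),
        ("CYP2C19*2", "star"),
        ("HLA-B*15:02", "hla"),
        ("NAT2*5", "star"),
    ])
    def test_syntax_rules(self, allele_id, expected):
        assert infer_allele_type(allele_id) == expected

    def test_uninferable_identifier_raises(self):
        with pytest.raises(CatalogError):
            infer_allele_type("chr1:123")


class TestClinicalAnnotations:
    HEADER = "allele_id\tgene\tdrug\tlevel\trisk_allele\n"

    def test_exact_duplicate_removed(self, tmp_path, two_drugs):
        p = _write(tmp_path, "ann.tsv", self.HEADER
                   + "rs1\tCYP2C9\twarfarin\t1A\tG\n"
                   + "rs1\tCYP2C9\twarfarin\t1A\tG\n"
                   + "rs2\tVKORC1\twarfarin\t1B\tT\n")
        records = catalog_io.read_clinical_annotations(p, two_drugs)
        assert len(records) == 2

    def test_star_allele_type_and_gene(self, tmp_path, two_drugs):
        p = _write(tmp_path, "ann.tsv", self.HEADER
                   + "CYP2C19*2\tCYP2C19\tritonavir\t1A\tCYP2C19*2\n")
        (rec,) = catalog_io.read_clinical_annotations(p, two_drugs)
        assert rec.allele_type == "star"
        assert rec.gene == "CYP2C19"

    def test_unlisted_drug_dropped(self, tmp_path, two_drugs):
        p = _write(tmp_path, "ann.tsv", self.HEADER
                   + "rs1\tCYP2C9\twarfarin\t1A\tG\n"
                   + "rs9\tDPYD\tcapecitabine\t1A\tT\n")
        records = catalog_io.read_clinical_annotations(p, two_drugs)
        assert [r.allele_id for r in records] == ["rs1"]

    def test_bad_level_rejected(self, tmp_path, two_drugs):
        p = _write(tmp_path, "ann.tsv", self.HEADER + "rs1\tCYP2C9\twarfarin\t5\tG\n")
        with pytest.raises(CatalogError, match="level"):
            catalog_io.read_clinical_annotations(p, two_drugs)

    def test_explicit_allele_type_must_agree(self, tmp_path, two_drugs):
        p = _write(tmp_path, "ann.tsv",
                   "allele_id\tallele_type\tgene\tdrug\tlevel\trisk_allele\n"
                   "rs1\tstar\tCYP2C9\twarfarin\t1A\tG\n")
        with pytest.raises(CatalogError, match="disagrees"):
            catalog_io.read_clinical_annotations(p, two_drugs)

    def test_same_pair_at_two_levels_both_kept(self, tmp_path, two_drugs):
        p = _write(tmp_path, "ann.tsv", self.HEADER
                   + "rs1\tCYP2C9\twarfarin\t1A\tG\n"
                   + "rs1\tCYP2C9\twarfarin\t3\tG\n")
        assert len(catalog_io.read_clinical_annotations(p, two_drugs)) == 2


class TestCtetCatalog:
    def test_duplicate_triple_removed(self, tmp_path, two_drugs):
        p = _write(tmp_path, "ctet.tsv", "drug\trole\tgene\n"
                   "warfarin\tenzyme\tCYP3A4\nwarfarin\tenzyme\tCYP3A4\n"
                   "warfarin\ttarget\tVKORC1\nritonavir\tenzyme\tCYP3A4\n")
        cat = catalog_io.read_ctet_catalog(p, two_drugs)
        assert len(cat.entries) == 3

    def test_gene_symbols_uppercased(self, tmp_path, two_drugs):
        p = _write(tmp_path, "ctet.tsv", "drug\trole\tgene\nwarfarin\tenzyme\tcyp3a4\n")
        cat = catalog_io.read_ctet_catalog(p, two_drugs)
        assert cat.genes_for("warfarin", "enzyme") == {"CYP3A4"}

    def test_unknown_role_rejected(self, tmp_path, two_drugs):
        p = _write(tmp_path, "ctet.tsv", "drug\trole\tgene\nwarfarin\treceptor\tVKORC1\n")
        with pytest.raises(CatalogError, match="role"):
            catalog_io.read_ctet_catalog(p, two_drugs)

    def test_drug_without_rows_is_zero_vector_candidate(self, tmp_path, two_drugs):
        p = _write(tmp_path, "ctet.tsv", "drug\trole\tgene\nwarfarin\tenzyme\tCYP2C9\n")
        cat = catalog_io.read_ctet_catalog(p, two_drugs)
        assert cat.elements_for("ritonavir") == frozenset()

    def test_dedup_idempotent_under_self_concatenation(self, tmp_path, two_drugs):
        body = "warfarin\tenzyme\tCYP2C9\nritonavir\ttarget\tABCB1\n"
        p1 = _write(tmp_path, "once.tsv", "drug\trole\tgene\n" + body)
        p2 = _write(tmp_path, "twice.tsv", "drug\trole\tgene\n" + body + body)
        assert (catalog_io.read_ctet_catalog(p1, two_drugs).entries
                == catalog_io.read_ctet_catalog(p2, two_drugs).entries)


# --- round-trip properties -------------------------------------------------

_gene = st.sampled_from(["CYP2C9", "CYP2C19", "VKORC1", "ABCB1", "SLCO1B1", "CYP3A4"])
_drugname = st.sampled_from(["warfarin", "ritonavir", "aspirin", "duloxetine"])


@st.composite
def catalogs(draw):
    triples = draw(st.sets(
        st.tuples(_drugname, st.sampled_from(CTET_ROLES), _gene), max_size=12
    ))
    return DrugGeneCatalog(entries=frozenset(triples))


@st.composite
def annotation_lists(draw):
    n = draw(st.integers(0, 8))
    recs = []
    seen = set()
    for i in range(n):
        rsid = f"rs{draw(st.integers(1, 500))}"
        drug = draw(_drugname)
        level = draw(st.sampled_from(EVIDENCE_LEVELS))
        if (rsid, drug, level) in seen:
            continue
        seen.add((rsid, drug, level))
        recs.append(ClinicalAnnotation(
            allele_id=rsid, allele_type="snp", gene=draw(_gene), drug=drug,
            level=level, risk_allele=draw(st.sampled_from("ACGT")),
        ))
    return recs


@settings(max_examples=100, derandomize=True)
@given(cat=catalogs())
def test_catalog_roundtrip_identity(cat, tmp_path_factory):
    tmp = tmp_path_factory.mktemp("rt")
    drugs = [Drug(n, ("antithrombotic",)) for n in
             ["warfarin", "ritonavir", "aspirin", "duloxetine"]]
    path = tmp / "cat.tsv"
    catalog_io.write_ctet_catalog(cat, path)
    assert catalog_io.read_ctet_catalog(path, drugs).entries == cat.entries


@settings(max_examples=100, derandomize=True)
@given(recs=annotation_lists())
def test_annotation_roundtrip_identity(recs, tmp_path_factory):
    tmp = tmp_path_factory.mktemp("rt")
    drugs = [Drug(n, ("antithrombotic",)) for n in
             ["warfarin", "ritonavir", "aspirin", "duloxetine"]]
    path = tmp / "ann.tsv"
    catalog_io.write_clinical_annotations(recs, path)
    assert catalog_io.read_clinical_annotations(path, drugs) == recs


def test_remaining_roundtrips(tmp_path, two_drugs):
    """Deleteriousness, diplotype and regimen tables survive a write/read cycle."""
    dels = [DeleteriousnessAnnotation("rs1", "CYP2C9", "nonsynonymous_exonic",
                                      "damaging", "benign", "missing")]
    catalog_io.write_deleteriousness(dels, tmp_path / "d.tsv")
    assert catalog_io.read_deleteriousness(tmp_path / "d.tsv") == dels

    dips = [DiplotypeCall("s1", "CYP2C19", "*1", "*2")]
    catalog_io.write_diplotypes(dips, tmp_path / "dip.tsv")
    assert catalog_io.read_diplotypes(tmp_path / "dip.tsv") == dips

    regs = [Regimen("covid", ("ritonavir", "warfarin"))]  # order must survive
    catalog_io.write_regimens(regs, tmp_path / "r.tsv")
    assert catalog_io.read_regimens(tmp_path / "r.tsv", two_drugs) == regs

    catalog_io.write_clinical_annotations([], tmp_path / "empty.tsv")
    assert catalog_io.read_clinical_annotations(tmp_path / "empty.tsv", two_drugs) == []


def test_reader_output_order_stable(tmp_path, two_drugs):
    text = ("drug\trole\tgene\nwarfarin\tenzyme\tCYP2C9\n"
            "ritonavir\ttarget\tABCB1\nwarfarin\tcarrier\tORM1\n")
    p = _write(tmp_path, "c.tsv", text)
    first = catalog_io.read_ctet_catalog(p, two_drugs)
    for _ in range(3):
        assert catalog_io.read_ctet_catalog(p, two_drugs).entries == first.entries
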