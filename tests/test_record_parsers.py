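"""Document parsers: PubMed XML, compendium HTML, model XML, clinical CSV."""

import pytest

from biocurate.errors import DialectError, ManifestError, ParseError
from biocurate.fixtures import FixtureSpec, generate
from biocurate.parsers import (
    DEFAULT_MANIFEST,
    ColumnManifest,
    parse_aneurisk_clinical,
    parse_biomodels,
    parse_malacards_diseases,
    parse_pubmed_articles,
)
from biocurate.query import search_query


class TestPubmedParser:
    def test_full_record_fields(self, pubmed_document):
        article = parse_pubmed_articles(pubmed_document)[0]
        assert article.pmid == "23371018"
        assert article.title == (
            "Non-dimensional analysis of retinal microaneurysms: "
            "critical threshold for treatment."
        )
        assert article.first_author == "Ezra Elishai"
        assert article.journal == (
            "Integrative biology : quantitative biosciences from nano to macro"
        )
        assert (article.volume, article.issue, article.year) == ("5", "3", 2013)
        assert article.doi == "10.1039/c3ib20259c"

    def test_missing_optionals_map_to_absent_marker(self, pubmed_document):
        article = parse_pubmed_articles(pubmed_document)[1]
        assert article.pmid == "10227670"
        assert article.volume == "194 (Pt 1)"
        assert article.issue is None
        assert article.doi is None
        assert article.year == 1999

    def test_document_order_preserved(self, pubmed_document):
        pmids = [a.pmid for a in parse_pubmed_articles(pubmed_document)]
        assert pmids == ["23371018", "10227670"]

    def test_empty_document_gives_empty_list(self):
        empty = generate(FixtureSpec(kind="pubmed-xml", records=()))
        assert parse_pubmed_articles(empty) == []

    def test_malformed_xml_is_a_parse_error_with_position(self):
        with pytest.raises(ParseError, match=r"line \d+"):
            parse_pubmed_articles(b"<PubmedArticleSet><oops</PubmedArticleSet>")

    def test_wrong_root_is_a_dialect_error(self):
        with pytest.raises(DialectError, match="PubmedArticleSet"):
            parse_pubmed_articles(b"<eSearchResult></eSearchResult>")

    def test_abstract_is_extracted_when_present(self):
        from biocurate.records import Article

        article = Article(pmid="1", title="T.", abstract="Retinal flow analysis.")
        parsed = parse_pubmed_articles(
            generate(FixtureSpec(kind="pubmed-xml", records=(article,)))
        )[0]
        assert parsed.abstract == "Retinal flow analysis."

    def test_reparsing_is_stable(self, pubmed_document):
        first = parse_pubmed_articles(pubmed_document)
        assert parse_pubmed_articles(pubmed_document) == first


class TestMalaCardsParser:
    def test_result_page_parses_in_page_order(self, malacards_document):
        diseases = parse_malacards_diseases(malacards_document)
        assert len(diseases) == 7
        assert diseases[0].name == (
            "Familial Thoracic Aortic Aneurysm and Dissection"
        )
        assert diseases[0].card_link == (
            "/card/familial_thoracic_aortic_aneurysm_and_dissection"
            "?search=aneurysm"
        )

    def test_non_card_anchors_are_ignored(self, malacards_document):
        for disease in parse_malacards_diseases(malacards_document):
            assert disease.card_link.startswith("/card/")

    def test_query_term_filters_links(self, malacards_document):
        query = search_query("MALA_CARDS", terms=["aneurysm"])
        assert len(parse_malacards_diseases(malacards_document, query)) == 7
        other = search_query("MALA_CARDS", terms=["stenosis"])
        assert parse_malacards_diseases(malacards_document, other) == []

    def test_empty_page_gives_empty_list(self):
        assert parse_malacards_diseases(b"") == []
        assert parse_malacards_diseases(b"<html><body></body></html>") == []

    def test_malformed_markup_is_tolerated(self):
        page = b'<html><body><a href="/card/x?search=y">Broken <b>page</a>'
        diseases = parse_malacards_diseases(page)
        assert len(diseases) == 1
        assert diseases[0].name == "Broken page"


class TestBiomodelsParser:
    @pytest.mark.parametrize(
        "index, model_id, prefix",
        [
            (
                0,
                "BIOMD0000000058",
                "The model reproduces the same amplitude antiphase calcium "
                "oscillations of coupled",
            ),
            (
                1,
                "BIOMD0000000291",
                "adsorption of albumin-bilirubin complex to the surface of "
                "carbon pyropolymer",
            ),
        ],
    )
    def test_demo_models_echo_id_and_description(
        self, demo_biomodels, index, model_id, prefix
    ):
        document = generate(
            FixtureSpec(kind="biomodels-xml", records=(demo_biomodels[index],))
        )
        model = parse_biomodels(document)
        assert model.model_id == model_id
        assert model.description.startswith(prefix)
        assert model.document == document  # payload retained opaquely

    def test_empty_description_maps_to_absent_marker(self):
        from biocurate.records import BioModel

        document = generate(
            FixtureSpec(
                kind="biomodels-xml",
                records=(BioModel(model_id="BIOMD0000000001", description=None),),
            )
        )
        assert parse_biomodels(document).description is None

    def test_missing_model_id_is_a_dialect_error(self):
        with pytest.raises(DialectError):
            parse_biomodels(b"<sbml><model/></sbml>")


class TestAneuriskParser:
    def test_printed_patient_fields(self, clinical_document):
        cases = {c.patient_id: c for c in parse_aneurisk_clinical(clinical_document)}
        c5 = cases["C0005"]
        assert (c5.sex, c5.age, c5.aneurysm_type, c5.location, c5.status) == (
            "F", 26, "LAT", "ICA", "R",
        )
        c8 = cases["C0008"]
        assert (c8.sex, c8.location, c8.status) == ("M", "ACA", "R")

    def test_row_count_matches_table(self, clinical_document):
        result = parse_aneurisk_clinical(clinical_document)
        n_rows = clinical_document.decode().strip().count("\n")  # header excluded
        assert len(result.cases) == n_rows
        assert result.diagnostics == []

    def test_invalid_status_rejected_with_row_diagnostic(self):
        table = (
            "id,sex,age,aneurysmType,aneurysmLocation,ruptureStatus\n"
            "C0001,F,30,TER,ICA,U\n"
            "C0002,F,31,TER,ICA,X\n"
        )
        result = parse_aneurisk_clinical(table)
        assert [c.patient_id for c in result.cases] == ["C0001"]
        assert len(result.diagnostics) == 1
        assert result.diagnostics[0].row == 2
        assert "status" in result.diagnostics[0].message

    def test_negative_age_rejected(self):
        table = (
            "id,sex,age,aneurysmType,aneurysmLocation,ruptureStatus\n"
            "C0001,F,-3,TER,ICA,U\n"
        )
        result = parse_aneurisk_clinical(table)
        assert result.cases == []
        assert "age" in result.diagnostics[0].message

    def test_missing_mandatory_column_fails_before_rows(self):
        with pytest.raises(ManifestError, match="ruptureStatus"):
            parse_aneurisk_clinical("id,sex,age,aneurysmType,aneurysmLocation\n")

    def test_manifest_requires_all_mandatory_fields(self):
        with pytest.raises(ManifestError, match="status"):
            ColumnManifest(columns={"patient_id": "id"})

    def test_decoders_translate_coded_columns(self):
        manifest = ColumnManifest(
            columns=dict(DEFAULT_MANIFEST.columns),
            decoders={"sex": {"FEMALE": "F", "MALE": "M"}},
        )
        table = (
            "id,sex,age,aneurysmType,aneurysmLocation,ruptureStatus\n"
            "C0001,FEMALE,30,TER,ICA,U\n"
        )
        assert parse_aneurisk_clinical(table, manifest).cases[0].sex == "F"
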