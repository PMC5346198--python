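"""Syntactic analysis of retrieved documents into typed records.

One parser per wire format: PubMed efetch XML, disease-compendium HTML
search pages, model-repository XML records, and clinical CSV tables.
STL geometry lives in :mod:`biocurate.stl`.

XML goes through lxml's strict parser (positions on error); HTML goes
through lxml's lenient tree builder because scraped pages are not
guaranteed well-formed; tables go through pandas.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field as dc_field
from typing import Optional

import pandas as pd
from lxml import etree, html as lxml_html

from .errors import DialectError, ManifestError, ParseError
from .query import Query
from .records import Article, Author, BioModel, Disease, case_violations, AneurysmCase

CARD_LINK_PATTERN = re.compile(r"^/card/[^?]+\?search=.+")
BIOMODEL_ID_PATTERN = re.compile(r"^BIOMD\d{10}$")


def _as_bytes(document) -> bytes:
    if isinstance(document, bytes):
        return document
    if isinstance(document, str):
        return document.encode("utf-8")
    raise TypeError(f"expected bytes or str document, got {type(document).__name__}")


def _parse_xml(document: bytes) -> etree._Element:
    try:
        return etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc


def _text(parent: etree._Element, path: str) -> Optional[str]:
    node = parent.find(path)
    if node is None:
        return None
    text = "".join(node.itertext()).strip()
    return text or None


def parse_pubmed_articles(document) -> list[Article]:
    """Parse an efetch article set into :class:`Article` records.

    Returns one record per ``PubmedArticle`` element in document order;
    optional bibliographic elements that are absent map to ``None``.
    """
    root = _parse_xml(_as_bytes(document))
    if root.tag != "PubmedArticleSet":
        raise DialectError(
            f"expected PubmedArticleSet root, got <{root.tag}>"
        )
    articles: list[Article] = []
    for elem in root.iter("PubmedArticle"):
        citation = elem.find("MedlineCitation")
        if citation is None:
            raise DialectError("PubmedArticle without MedlineCitation")
        pmid = _text(citation, "PMID")
        art = citation.find("Article")
        if pmid is None or art is None:
            raise DialectError("article record missing PMID or Article element")
        authors = []
        for author in art.findall("AuthorList/Author"):
            last = _text(author, "LastName")
            fore = _text(author, "ForeName") or _text(author, "Initials")
            if last:
                authors.append(Author(last_name=last, fore_name=fore or ""))
        doi = None
        for eloc in art.findall("ELocationID"):
            if eloc.get("EIdType") == "doi":
                doi = (eloc.text or "").strip() or None
        year_text = _text(art, "Journal/JournalIssue/PubDate/Year")
        articles.append(
            Article(
                pmid=pmid,
                title=_text(art, "ArticleTitle") or "",
                authors=tuple(authors),
                journal=_text(art, "Journal/Title"),
                volume=_text(art, "Journal/JournalIssue/Volume"),
                issue=_text(art, "Journal/JournalIssue/Issue"),
                year=int(year_text) if year_text else None,
                doi=doi,
                abstract=_text(art, "Abstract/AbstractText"),
            )
        )
    return articles


def parse_malacards_diseases(document, query: Query | None = None) -> list[Disease]:
    """Extract disease hits from a search-results page.

    A hit is any anchor whose ``href`` is a relative card link of the form
    ``/card/<slug>?search=<term>``; anchor text supplies the disease name.
    Page order is preserved and non-card anchors are ignored.  When a
    query is given, only links produced by its first search term are kept.
    """
    payload = _as_bytes(document)
    if not payload.strip():
        return []
    try:
        tree = lxml_html.fromstring(payload)
    except etree.ParserError as exc:
        raise ParseError(f"cannot build HTML tree: {exc}") from exc
    wanted_term = query.terms[0] if query is not None and query.terms else None
    diseases: list[Disease] = []
    for anchor in tree.iterfind(".//a[@href]"):
        href = anchor.get("href", "")
        if not CARD_LINK_PATTERN.match(href):
            continue
        if wanted_term is not None and not href.endswith(f"search={wanted_term}"):
            continue
        name = anchor.text_content().strip()
        if name:
            diseases.append(Disease(name=name, card_link=href))
    return diseases


def parse_biomodels(document) -> BioModel:
    """Parse a model-repository XML record.

    The payload is retained opaquely on the returned record; only the model
    identifier and the human-readable description (notes) are lifted out.
    """
    payload = _as_bytes(document)
    root = _parse_xml(payload)
    model_elem = None
    for elem in root.iter():
        if etree.QName(elem).localname == "model":
            model_elem = elem
            break
    if model_elem is None or not model_elem.get("id"):
        raise DialectError("document carries no model element with an id")
    model_id = model_elem.get("id")
    if not BIOMODEL_ID_PATTERN.match(model_id):
        raise DialectError(f"model id {model_id!r} does not match BIOMD+10 digits")
    description = None
    for elem in model_elem.iter():
        if etree.QName(elem).localname == "notes":
            description = "".join(elem.itertext()).strip() or None
            break
    return BioModel(model_id=model_id, description=description, document=payload)


@dataclass(frozen=True)
class ColumnManifest:
    """Maps case fields onto the source table's column names.

    ``decoders`` translate coded column values (e.g. ``"FEMALE"`` -> ``"F"``)
    into the canonical vocabulary; fields without a decoder are taken
    verbatim.  Every mandatory case field must have a source column.
    """

    columns: dict
    decoders: dict = dc_field(default_factory=dict)

    MANDATORY = ("patient_id", "sex", "age", "aneurysm_type", "location", "status")

    def __post_init__(self) -> None:
        missing = [f for f in self.MANDATORY if f not in self.columns]
        if missing:
            raise ManifestError(
                f"manifest missing source columns for fields: {', '.join(missing)}"
            )

    def decode(self, field_name: str, raw):
        decoder = self.decoders.get(field_name)
        if decoder is None:
            return raw
        if callable(decoder):
            return decoder(raw)
        return decoder.get(raw, raw)


#: Column naming of the clinical tables the fixture generator emits,
#: modelled on the Aneurisk repository's per-case metadata.
DEFAULT_MANIFEST = ColumnManifest(
    columns={
        "patient_id": "id",
        "sex": "sex",
        "age": "age",
        "aneurysm_type": "aneurysmType",
        "location": "aneurysmLocation",
        "status": "ruptureStatus",
    }
)


@dataclass(frozen=True)
class RowDiagnostic:
    """A rejected table row: 1-based data row number plus the reason."""

    row: int
    message: str


@dataclass
class ClinicalTable:
    """Result of parsing a clinical table: accepted cases plus per-row
    diagnostics for rejected records."""

    cases: list
    diagnostics: list

    def __iter__(self):
        return iter(self.cases)

    def __len__(self) -> int:
        return len(self.cases)


def parse_aneurisk_clinical(
    table, manifest: ColumnManifest = DEFAULT_MANIFEST
) -> ClinicalTable:
    """Parse a delimited clinical table into aneurysm case records.

    The manifest is checked against the header before any row is read.
    Rows that violate the case invariants (unknown codes, negative age)
    are rejected with row-numbered diagnostics; valid rows are returned
    in table order.
    """
    if isinstance(table, bytes):
        table = table.decode("utf-8")
    frame = pd.read_csv(io.StringIO(table), dtype=str, keep_default_na=False)
    missing = [c for c in manifest.columns.values() if c not in frame.columns]
    if missing:
        raise ManifestError(
            f"table header missing manifest columns: {', '.join(missing)}"
        )
    cases: list[AneurysmCase] = []
    diagnostics: list[RowDiagnostic] = []
    for row_index in range(len(frame)):
        row_number = row_index + 1
        row = frame.iloc[row_index]
        values = {
            field_name: manifest.decode(field_name, row[column])
            for field_name, column in manifest.columns.items()
        }
        try:
            age = int(values["age"])
        except (TypeError, ValueError):
            age = values["age"]
        violations = case_violations(
            values["sex"], age, values["aneurysm_type"], values["status"]
        )
        if not values["patient_id"]:
            violations.append("patient id must be non-empty")
        if violations:
            for violation in violations:
                diagnostics.append(RowDiagnostic(row=row_number, message=violation))
            continue
        cases.append(
            AneurysmCase(
                patient_id=values["patient_id"],
                sex=values["sex"],
                age=age,
                aneurysm_type=values["aneurysm_type"],
                location=values["location"],
                status=values["status"],
            )
        )
    return ClinicalTable(cases=cases, diagnostics=diagnostics)
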