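"""Synthetic-document generation for every supported wire format.

The generators emit the same formats the parsers read — PubMed-dialect
efetch XML, disease-compendium HTML result pages, model-repository XML,
clinical CSV tables and STL geometry — so the whole framework can be
exercised with no network access.  The contract is the round trip:
``parse(generate(spec))`` recovers the payload records field for field.

Documents are deterministic: the same spec (records + seed) always yields
byte-identical output.  When a spec carries no explicit records, they are
drawn from a seeded generator (word-list free text, unit-sphere-perturbation
geometry).
"""

from __future__ import annotations

import csv
import html as html_escape
import io
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lxml import etree

from .errors import RetrievalError
from .records import (
    ANEURYSM_TYPES,
    SEX_CODES,
    STATUS_CODES,
    AneurysmCase,
    Article,
    Author,
    BioModel,
    Disease,
    TriMesh,
)
from .stl import write_stl_ascii, write_stl_binary
from .urls import StructuredRequest

FORMAT_KINDS = (
    "pubmed-xml",
    "malacards-html",
    "biomodels-xml",
    "aneurisk-csv",
    "stl-ascii",
    "stl-binary",
)

#: Word list for seeded free text.
_WORDS = (
    "aneurysm vascular cerebral arterial retinal flow shear stress wall "
    "dynamics model analysis rupture risk saccular fusiform basilar carotid "
    "geometry morphology patient clinical imaging pressure velocity gradient "
    "dome neck ratio threshold treatment outcome cohort segment vessel lumen "
    "hemodynamic simulation oscillation calcium endothelial"
).split()


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: a format kind, the records to encode, and a seed
    used when records (or their free text/geometry) must be invented."""

    kind: str
    records: Optional[tuple] = None
    seed: int = 0
    n_records: int = 1

    def resolved_records(self) -> tuple:
        if self.records is not None:
            return tuple(self.records)
        return tuple(random_records(self.kind, self.n_records, self.seed))


# ---------------------------------------------------------------------------
# Per-format encoders.

def _sub(parent, tag: str, text: Optional[str] = None, **attrs):
    elem = etree.SubElement(parent, tag, **attrs)
    if text is not None:
        elem.text = text
    return elem


def encode_pubmed_xml(articles: Sequence[Article]) -> bytes:
    root = etree.Element("PubmedArticleSet")
    for article in articles:
        citation = _sub(_sub(root, "PubmedArticle"), "MedlineCitation")
        _sub(citation, "PMID", article.pmid)
        art = _sub(citation, "Article")
        journal = _sub(art, "Journal")
        if article.journal is not None:
            _sub(journal, "Title", article.journal)
        issue_elem = _sub(journal, "JournalIssue")
        if article.volume is not None:
            _sub(issue_elem, "Volume", article.volume)
        if article.issue is not None:
            _sub(issue_elem, "Issue", article.issue)
        if article.year is not None:
            _sub(_sub(issue_elem, "PubDate"), "Year", str(article.year))
        _sub(art, "ArticleTitle", article.title)
        if article.doi is not None:
            _sub(art, "ELocationID", article.doi, EIdType="doi")
        if article.abstract is not None:
            _sub(_sub(art, "Abstract"), "AbstractText", article.abstract)
        if article.authors:
            author_list = _sub(art, "AuthorList")
            for author in article.authors:
                author_elem = _sub(author_list, "Author")
                _sub(author_elem, "LastName", author.last_name)
                if author.fore_name:
                    _sub(author_elem, "ForeName", author.fore_name)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def encode_malacards_html(diseases: Sequence[Disease]) -> bytes:
    items = "\n".join(
        '      <li class="searchResultTitle">'
        f'<a href="{html_escape.escape(d.card_link)}">'
        f"{html_escape.escape(d.name)}</a></li>"
        for d in diseases
    )
    page = (
        "<!DOCTYPE html>\n<html>\n  <head><title>Search results</title></head>\n"
        "  <body>\n"
        '    <a href="/home">Home</a>\n'
        '    <a href="/about">About</a>\n'
        "    <ul>\n" + (items + "\n" if items else "") + "    </ul>\n"
        "  </body>\n</html>\n"
    )
    return page.encode("utf-8")


SBML_NS = "http://www.sbml.org/sbml/level2/version4"
XHTML_NS = "http://www.w3.org/1999/xhtml"


def encode_biomodels_xml(models: Sequence[BioModel]) -> bytes:
    if len(models) > 1:
        raise ValueError("a model record document holds exactly one model")
    root = etree.Element(f"{{{SBML_NS}}}sbml", level="2", version="4")
    if models:
        model = models[0]
        model_elem = etree.SubElement(
            root, f"{{{SBML_NS}}}model", id=model.model_id
        )
        if model.description is not None:
            notes = etree.SubElement(model_elem, f"{{{SBML_NS}}}notes")
            body = etree.SubElement(notes, f"{{{XHTML_NS}}}body")
            p = etree.SubElement(body, f"{{{XHTML_NS}}}p")
            p.text = model.description
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


#: Fixture clinical-table header (see parsers.DEFAULT_MANIFEST).
CSV_COLUMNS = ("id", "sex", "age", "aneurysmType", "aneurysmLocation", "ruptureStatus")


def encode_aneurisk_csv(cases: Sequence[AneurysmCase]) -> bytes:
    out = io.StringIO()
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for case in cases:
        writer.writerow(
            (
                case.patient_id,
                case.sex,
                case.age,
                case.aneurysm_type,
                case.location,
                case.status,
            )
        )
    return out.getvalue().encode("utf-8")


def generate(spec: FixtureSpec) -> bytes:
    """Encode a fixture spec into document bytes in its wire format."""
    records = spec.resolved_records()
    if spec.kind == "pubmed-xml":
        return encode_pubmed_xml(records)
    if spec.kind == "malacards-html":
        return encode_malacards_html(records)
    if spec.kind == "biomodels-xml":
        return encode_biomodels_xml(records)
    if spec.kind == "aneurisk-csv":
        return encode_aneurisk_csv(records)
    if spec.kind == "stl-ascii":
        (mesh,) = records
        return write_stl_ascii(mesh)
    if spec.kind == "stl-binary":
        (mesh,) = records
        return write_stl_binary(mesh)
    raise ValueError(f"unknown fixture format kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# Seeded record generators.

def _words(rng: np.random.Generator, low: int, high: int) -> str:
    n = int(rng.integers(low, high + 1))
    return " ".join(_WORDS[i] for i in rng.integers(0, len(_WORDS), size=n))


def random_article(rng: np.random.Generator) -> Article:
    pmid = str(int(rng.integers(1, 10**8)))
    authors = tuple(
        Author(
            last_name=_WORDS[int(rng.integers(0, len(_WORDS)))].capitalize(),
            fore_name="".join(
                chr(ord("A") + int(c)) for c in rng.integers(0, 26, size=2)
            ),
        )
        for _ in range(int(rng.integers(1, 4)))
    )
    return Article(
        pmid=pmid,
        title=_words(rng, 3, 8).capitalize() + ".",
        authors=authors,
        journal=_words(rng, 2, 4).capitalize(),
        volume=str(int(rng.integers(1, 200))) if rng.random() < 0.9 else None,
        issue=str(int(rng.integers(1, 12))) if rng.random() < 0.7 else None,
        year=int(rng.integers(1950, 2026)) if rng.random() < 0.9 else None,
        doi=f"10.{int(rng.integers(1000, 9999))}/x{int(rng.integers(0, 10**6))}"
        if rng.random() < 0.7
        else None,
        abstract=_words(rng, 10, 30).capitalize() + "." if rng.random() < 0.5 else None,
    )


def random_disease(rng: np.random.Generator, search_term: str = "aneurysm") -> Disease:
    name = _words(rng, 2, 5).title()
    slug = re.sub(r"[^a-z0-9]+", "_", name.lower()).strip("_")
    return Disease(
        name=name, card_link=f"/card/{slug}?search={search_term}"
    )


def random_biomodel(rng: np.random.Generator) -> BioModel:
    model_id = f"BIOMD{int(rng.integers(0, 10**10)):010d}"
    description = _words(rng, 8, 25) if rng.random() < 0.85 else None
    return BioModel(model_id=model_id, description=description)


_LOCATIONS = ("ICA", "ACA", "MCA", "BAS", "PCA")


def random_case(rng: np.random.Generator) -> AneurysmCase:
    return AneurysmCase(
        patient_id=f"C{int(rng.integers(0, 10000)):04d}",
        sex=SEX_CODES[int(rng.integers(0, len(SEX_CODES)))],
        age=int(rng.integers(0, 100)),
        aneurysm_type=ANEURYSM_TYPES[int(rng.integers(0, len(ANEURYSM_TYPES)))],
        location=_LOCATIONS[int(rng.integers(0, len(_LOCATIONS)))],
        status=STATUS_CODES[int(rng.integers(0, len(STATUS_CODES)))],
    )


def random_mesh(rng: np.random.Generator, n_facets: int = 8) -> TriMesh:
    """A triangle soup of unit-sphere points with radial perturbations,
    loosely emulating a saccular aneurysm surface patch."""
    points = rng.normal(size=(n_facets, 3, 3))
    norms = np.linalg.norm(points, axis=-1, keepdims=True)
    norms[norms == 0] = 1.0
    points = points / norms * (1.0 + 0.1 * rng.random(size=(n_facets, 3, 1)))
    edge1 = points[:, 1] - points[:, 0]
    edge2 = points[:, 2] - points[:, 0]
    normals = np.cross(edge1, edge2)
    lengths = np.linalg.norm(normals, axis=-1, keepdims=True)
    degenerate = (lengths < 1e-12).ravel()
    normals[degenerate] = (0.0, 0.0, 1.0)
    lengths[lengths < 1e-12] = 1.0
    normals = normals / lengths
    # float32 grid so both STL dialects carry the coordinates exactly
    return TriMesh(
        vertices=points.astype(np.float32).astype(np.float64),
        normals=normals.astype(np.float32).astype(np.float64),
    )


def random_records(kind: str, n: int, seed: int) -> list:
    """Draw ``n`` valid records for a format kind from a seeded generator.

    Records with identity keys (pmid, card link, model id, patient id) are
    de-duplicated so a generated document never encodes key collisions.
    """
    rng = np.random.default_rng(seed)
    makers = {
        "pubmed-xml": (random_article, lambda a: a.pmid),
        "malacards-html": (random_disease, lambda d: d.card_link),
        "biomodels-xml": (random_biomodel, lambda m: m.model_id),
        "aneurisk-csv": (random_case, lambda c: c.patient_id),
    }
    if kind in ("stl-ascii", "stl-binary"):
        return [random_mesh(rng, n_facets=max(1, 4 * n))]
    if kind not in makers:
        raise ValueError(f"unknown fixture format kind {kind!r}")
    maker, key = makers[kind]
    records: list = []
    seen: set[str] = set()
    while len(records) < n:
        record = maker(rng)
        if key(record) in seen:
            continue
        seen.add(key(record))
        records.append(record)
    return records


# ---------------------------------------------------------------------------
# Fixture transport.

class FixtureTransport:
    """A transport answering only a fixed URL -> document mapping.

    Values may be raw bytes or :class:`FixtureSpec` instances (encoded on
    construction, so repeated fetches return identical bytes).  Unmapped
    URLs raise :class:`RetrievalError`, like a dead link would.
    """

    def __init__(self, mapping: dict):
        self._documents: dict[str, bytes] = {}
        for url, value in mapping.items():
            self._documents[url] = (
                value if isinstance(value, bytes) else generate(value)
            )

    def fetch(self, request: StructuredRequest) -> bytes:
        url = request.url if isinstance(request, StructuredRequest) else request
        try:
            return self._documents[url]
        except KeyError:
            raise RetrievalError(url, "no fixture mapped for this URL") from None


def fixture_transport(mapping: dict) -> FixtureTransport:
    """Build a :class:`FixtureTransport` from a URL -> spec/bytes mapping."""
    return FixtureTransport(mapping)
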