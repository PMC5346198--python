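"""The worked demonstration: a specialized aneurysm database from fixtures.

Aneurysms are vascular pathologies whose clinical weight depends on
location and geometry; a curation effort around them needs to pull
together literature records, associated human diseases, mathematical
models of the underlying biology, and per-patient clinical data with 3-D
surface geometry.  This module carries a small, fully worked instance of
that database: canned records for two retinal-microaneurysm articles,
seven aneurysm-associated diseases, two calcium/transport models, and
five clinical cases, together with the fixture documents and transport
that let the whole retrieval pipeline run offline.
"""

from __future__ import annotations

import numpy as np

from . import fixtures, schema
from .parsers import (
    parse_aneurisk_clinical,
    parse_biomodels,
    parse_malacards_diseases,
    parse_pubmed_articles,
)
from .query import Query, fetch_query, search_query
from .records import AneurysmCase, Article, Author, BioModel, Disease
from .stl import write_stl_binary
from .store import EntityStore
from .urls import (
    build_biomodels_request,
    build_entrez_url,
    build_malacards_url,
    execute,
)

DEMO_PMIDS = ("23371018", "10227670")


def demo_articles() -> list[Article]:
    return [
        Article(
            pmid="23371018",
            title=(
                "Non-dimensional analysis of retinal microaneurysms: "
                "critical threshold for treatment."
            ),
            authors=(Author("Ezra", "Elishai"),),
            journal="Integrative biology : quantitative biosciences from nano to macro",
            volume="5",
            issue="3",
            year=2013,
            doi="10.1039/c3ib20259c",
        ),
        Article(
            pmid="10227670",
            title=(
                "Three dimensional analysis of microaneurysms in the "
                "human diabetic retina."
            ),
            authors=(Author("Moore", "JJ"),),
            journal="Journal of anatomy",
            volume="194 (Pt 1)",
            issue=None,
            year=1999,
            doi=None,
        ),
    ]


_DISEASE_NAMES = (
    "Familial Thoracic Aortic Aneurysm and Dissection",
    "Coronary Aneurysm",
    "Angiopathy, Hereditary, with Nephropathy, Aneurysms, and Muscle Cramps",
    "Aneurysmal Bone Cysts",
    "Intracranial Berry Aneurysm",
    "Cerebral Aneurysms",
    "Loeys-Dietz Syndrome",
)

_DISEASE_SLUGS = (
    "familial_thoracic_aortic_aneurysm_and_dissection",
    "coronary_aneurysm",
    "angiopathy_hereditary_with_nephropathy_aneurysms_and_muscle_cramps",
    "aneurysmal_bone_cysts",
    "intracranial_berry_aneurysm",
    "cerebral_aneurysms",
    "loeys_dietz_syndrome",
)


def demo_diseases(search_term: str = "aneurysm") -> list[Disease]:
    return [
        Disease(name=name, card_link=f"/card/{slug}?search={search_term}")
        for name, slug in zip(_DISEASE_NAMES, _DISEASE_SLUGS)
    ]


def demo_biomodels() -> list[BioModel]:
    return [
        BioModel(
            model_id="BIOMD0000000058",
            description=(
                "The model reproduces the same amplitude antiphase calcium "
                "oscillations of coupled intracellular oscillators."
            ),
        ),
        BioModel(
            model_id="BIOMD0000000291",
            description=(
                "adsorption of albumin-bilirubin complex to the surface of "
                "carbon pyropolymer during hemoperfusion."
            ),
        ),
    ]


_CASE_ROWS = (
    ("C0004", "F", 60, "TER", "ICA", "U"),
    ("C0005", "F", 26, "LAT", "ICA", "R"),
    ("C0006", "F", 45, "LAT", "ICA", "U"),
    ("C0007", "F", 44, "LAT", "ICA", "U"),
    ("C0008", "M", 68, "TER", "ACA", "R"),
)


def demo_cases() -> list[AneurysmCase]:
    return [
        AneurysmCase(
            patient_id=pid, sex=sex, age=age, aneurysm_type=typ,
            location=loc, status=status,
        )
        for pid, sex, age, typ, loc, status in _CASE_ROWS
    ]


def demo_queries() -> dict[str, Query]:
    """The queries the demonstration issues against each repository."""
    return {
        "pubmed": fetch_query("PUBMED", DEMO_PMIDS),
        "malacards": search_query("MALA_CARDS", terms=["aneurysm"]),
        "biomodels": [
            fetch_query("BIOMODELS", [m.model_id]) for m in demo_biomodels()
        ],
    }


def demo_transport() -> fixtures.FixtureTransport:
    """Fixture transport answering exactly the demonstration URLs."""
    queries = demo_queries()
    mapping = {
        build_entrez_url(queries["pubmed"]).url: fixtures.FixtureSpec(
            kind="pubmed-xml", records=tuple(demo_articles())
        ),
        build_malacards_url(queries["malacards"]).url: fixtures.FixtureSpec(
            kind="malacards-html", records=tuple(demo_diseases())
        ),
    }
    for query, model in zip(queries["biomodels"], demo_biomodels()):
        mapping[build_biomodels_request(query).url] = fixtures.FixtureSpec(
            kind="biomodels-xml", records=(model,)
        )
    return fixtures.fixture_transport(mapping)


def demo_clinical_table() -> bytes:
    return fixtures.generate(
        fixtures.FixtureSpec(kind="aneurisk-csv", records=tuple(demo_cases()))
    )


def curate_demo_store(
    store_path: str = ":memory:",
    geometry_dir=None,
    seed: int = 0,
) -> EntityStore:
    """Run the whole curation pipeline offline and return the filled store.

    Retrieves and parses every demonstration document through the fixture
    transport, links each clinical case to the retrieved articles, diseases
    and models, attaches a seeded stand-in for the externally computed
    rupture-risk score, optionally writes per-case STL geometry beside the
    store, and persists everything.
    """
    transport = demo_transport()
    queries = demo_queries()

    articles = parse_pubmed_articles(
        execute(build_entrez_url(queries["pubmed"]), transport)
    )
    diseases = parse_malacards_diseases(
        execute(build_malacards_url(queries["malacards"]), transport),
        queries["malacards"],
    )
    models = [
        parse_biomodels(execute(build_biomodels_request(q), transport))
        for q in queries["biomodels"]
    ]
    cases = parse_aneurisk_clinical(demo_clinical_table()).cases

    rng = np.random.default_rng(seed)
    store = EntityStore(store_path)
    for case in cases:
        for article in articles:
            schema.associate(case, article, schema.CASE_ARTICLE)
        for disease in diseases:
            schema.associate(case, disease, schema.CASE_DISEASE)
        for model in models:
            schema.associate(case, model, schema.CASE_MODEL)
        schema.attach_risk_score(case, round(float(rng.uniform(0.0, 1.0)), 3))
        if geometry_dir is not None:
            mesh = fixtures.random_mesh(rng, n_facets=16)
            path = f"{geometry_dir}/{case.patient_id}.stl"
            with open(path, "wb") as fh:
                fh.write(write_stl_binary(mesh))
            case.geometry_ref = f"{case.patient_id}.stl"
        store.persist(case)
    return store
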