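# biocurate

A framework for the rapid curation of **specialized biological databases**
— the community- or lab-specific datasets that mix newly generated data
with records derived from established repositories. It is written for
researchers who can define an object-oriented data model and want to load
it from public sources and persist it without writing repository clients,
parsers, or relational plumbing themselves.

The framework is five cooperating layers:

1. **Query model** — a `Query` object captures search intent (repository,
   free-text terms, field constraints, record identifiers, SEARCH vs
   FETCH) over an expandable repository catalogue with controlled
   vocabularies for advanced-search fields.
2. **Structured URL interfaces** — repositories with a fixed URL syntax
   are driven by translating queries into those URLs. For NCBI's Entrez
   eUtils, a FETCH becomes
   `efetch.fcgi?db=<db>&id=<id,id,...>&retmode=xml` and a SEARCH becomes
   `esearch.fcgi?db=<db>&term=<value>[<tag>]+...+<term>+AND+<term>&retmode=xml&rettype=uilist`.
   Disease-compendium (MalaCards-style) and model-repository
   (BioModels-style) endpoints are configurable templates. Retrieval goes
   through a pluggable transport, so everything also runs offline against
   in-memory fixtures.
3. **Record parsers** — typed parsing of the retrieved documents: PubMed
   efetch XML → `Article`, HTML search-result pages → `Disease`, model XML
   records → `BioModel`, clinical CSV tables (column-manifest driven) →
   `AneurysmCase`, and STL surface geometry (ASCII and binary, auto-detected)
   → `TriMesh`.
4. **Entity schema** — the user's object schema: entity kinds, their
   persistable fields, and labelled many-to-many associations (e.g.
   case–article, case–disease, case–model), plus scalar attributes such as
   an externally computed rupture-risk score.
5. **Persistent agent** — an ORM-style mapping of that schema onto an
   embedded single-file relational store (SQLite), queried with a small
   SQL-like language:
   `SELECT <alias> FROM <Kind> <alias> [WHERE <alias>.<field> = :<param>]`.

The worked demonstration curates a database of cerebral-aneurysm cases —
clinical records linked to literature, associated human diseases,
mathematical models, 3-D aneurysm geometry, and a risk score.

## Worked example

```python
import biocurate as bc
from biocurate import demo

# 1. A query object, translated to a structured URL
query = bc.fetch_query("PUBMED", ["23371018", "10227670"])
print(bc.build_entrez_url(query).url)

# 2. Retrieve (offline, via the fixture transport), parse, persist
articles = bc.parse_pubmed_articles(
    bc.execute(bc.build_entrez_url(query), demo.demo_transport())
)
store = bc.EntityStore("aneurysm.db")
for article in articles:
    store.persist(article)

# 3. Query the store and render record cards
print(bc.render_cards(store.query("SELECT a FROM Article a")))
```

This prints:

```
http://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=pubmed&id=23371018,10227670&retmode=xml
---------------------------------------
ID: 23371018
TITLE: Non-dimensional analysis of retinal microaneurysms: critical threshold for treatment.
AUTHOR: Ezra Elishai
JOURNAL: Integrative biology : quantitative biosciences from nano to macro 5(3), 2013, DOI: 10.1039/c3ib20259c
---------------------------------------
ID: 10227670
TITLE: Three dimensional analysis of microaneurysms in the human diabetic retina.
AUTHOR: Moore JJ
JOURNAL: Journal of anatomy 194 (Pt 1)(?), 1999, DOI: ?
---------------------------------------
```

Each card is one bibliographic record: PMID, title, first author
("LastName FirstName"), and a journal line `<journal> <volume>(<issue>),
<year>, DOI: <doi>` where `?` marks values absent from the source record
(the 1999 record carries no issue number or DOI).

The full demonstration database — 2 articles, 7 diseases, 2 models and 5
clinical cases, fully cross-associated — is one call
(`demo.curate_demo_store("aneurysm.db")`) or one shell command:

```sh
$ biocurate demo --store aneurysm.db
Article: 2 row(s)
Disease: 7 row(s)
Model: 2 row(s)
Aneurysm: 5 row(s)
```

after which a patient-centric query returns a case together with every
associated article, disease and model:

```python
(case,) = store.query(
    "SELECT p FROM Aneurysm p WHERE p.patientID = :patientID",
    {"patientID": "C0004"},
)
```

The CLI also exposes `search` (build/execute a repository query;
`--url-only` prints the structured URL), `persist`, `query`, `render`,
and `fixtures` (emit synthetic documents in any supported wire format).

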