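# Methods

## The data model

The framework treats specialized-database curation as three data
streams: retrieval from established repositories, incorporation of
user-generated data, and persistence of a user-defined object schema.
The in-memory model is object-centred — typed entities (`Article`,
`Disease`, `BioModel`, `AneurysmCase`, `TriMesh`) with labelled
many-to-many associations — and the persistent agent maps it to a
relational image: one table per entity kind (a column per persisted
field, primary-keyed on the kind's key field) and one table per
association label (source/target key pairs with foreign keys and a
uniqueness constraint). Upsert-on-key makes persistence idempotent;
cascade-persist of association targets keeps the relational image free
of dangling references by construction, and `EntityStore.check_integrity`
audits it directly against the tables.

## Query objects and URL generation

A `Query` is immutable with value semantics: repository name, SEARCH or
FETCH, ordered terms, ordered identifiers, ordered (field, value)
constraints, and a term connector (AND default, OR supported; NOT is
not). Validation returns violations as data rather than raising, so a
front end can report all problems at once.

Entrez URL generation is deterministic with a fixed parameter order
(`db`, `id`/`term`, `retmode`, `rettype`). The term string renders field
constraints first as `<value>[<tag>]`, then free-text terms joined by
`+AND+`/`+OR+`; brackets and `+` separators are emitted literally and
spaces inside values become `+`. That wire encoding maps space and the
separator to the same byte, so the build/parse inversion
(`parse_entrez_url`) is defined — and property-tested — only over
queries whose tokens contain no spaces, brackets, or literal connector
tokens. The eUtils base URL defaults to the classic
`http://eutils.ncbi.nlm.nih.gov/entrez/eutils` host and is a config
entry (the live service answers on https today). Disease-compendium and
model-repository search URLs are not a published, stable grammar, so
they are endpoint templates in a plain-text config file rather than
hard-coded syntaxes.

Transports are injected. The library core never opens a connection: the
live transport (urllib-based) and the in-memory fixture transport are
interchangeable, and the test suite and demonstration run entirely on
fixtures.

## Parsers

* **PubMed XML** (strict lxml): one `Article` per `PubmedArticle`
  element, document order preserved. Absent optional elements map to
  `None` internally; the `?` seen on rendered cards is applied only at
  render time. Abstracts are lifted from the fetched document itself —
  no second request is issued.
* **HTML result pages** (lenient lxml.html): a disease hit is any anchor
  whose href matches `/card/<slug>?search=<term>`; other anchors are
  navigation and are ignored. Scraped pages are not guaranteed
  well-formed, so the tree builder is error-tolerant.
* **Model XML**: the model id and notes text are lifted out
  (namespace-agnostic match on local names `model`/`notes`); the payload
  itself stays opaque on the record — no semantic interpretation of the
  model document is attempted.
* **Clinical CSV** (pandas): a `ColumnManifest` externalizes the mapping
  from case fields to source columns plus per-column value decoders,
  because clinical tables from different repositories name and encode
  columns differently. The manifest is checked against the header before
  any row is read. Rows violating the case invariants (sex `F|M`, type
  `TER|LAT`, status `U|R`, non-negative integer age) are rejected with
  1-based row-numbered diagnostics while valid rows are still returned —
  curation should not stop at the first bad record.
* **STL**: both dialects, auto-detected (ASCII starts with `solid` and
  contains `facet`; otherwise binary). The binary facet count is checked
  against `84 + 50·n` before decoding, so truncated payloads raise a
  dedicated error instead of yielding a partial mesh. Non-finite
  coordinates are rejected by the `TriMesh` container, not silently
  stored. The reader/writer pair is implemented on numpy structured
  arrays; tests cross-check the reader against an independent mesh
  library.

## Query language

The persisted store answers
`SELECT <alias> FROM <Kind> <alias> [WHERE <alias>.<field> = :<param>]`
— a single entity kind with at most one equality predicate bound to a
named parameter. Keywords are case-insensitive, aliases case-sensitive,
string comparison exact and case-sensitive, and syntax errors carry the
character offset of the offending token. Joins are deliberately absent:
association traversal on the returned case objects replaces them, and
the patient-centric query materialises every associated article, disease
and model on the result. Result order is insertion order (via rowid) so
queries are deterministic. The clinical case kind is registered under
the name `Aneurysm` with key field `patientID`, which is how its users
phrase the query.

## Fixtures and what they do (and do not) show

The fixture generators emit minimal but structurally faithful documents
in each wire format — the element names and nesting a consumer of the
real services would see — and the contract is the round trip:
`parse(generate(records)) == records`, enforced by property tests with
hundreds of randomized payloads per format. Free text is drawn from a
seeded domain word list and geometry from seeded unit-sphere
perturbations, so identical specs produce byte-identical documents.

Fixtures emulate document *structure*, not service behaviour: no
pagination, error payloads, rate limits, session state, or the full
PubMed DTD (MeSH terms, grants, chemicals are out of scope). Passing
tests therefore demonstrate that the pipeline is correct for
well-formed records in the supported dialects; they do not certify
robustness against every variant the live services can emit, and the
asserted HTML anchor pattern is an interface contract rather than a
scrape of any particular page version.

## Numerical and design choices

* Binary STL stores float32; generated meshes are snapped to the float32
  grid so both dialects carry coordinates exactly, and dialect agreement
  is asserted at 1e-6 per coordinate (well above float32 rounding at
  unit scale). ASCII output uses `%.9e`, enough to round-trip float32
  exactly.
* Floats cross the relational boundary as SQLite REALs (IEEE doubles),
  so persistence round trips are exact; tests assert 1e-12.
* Model-description cards truncate at 80 characters with a trailing
  ellipsis; the limit is a render-time knob and stored text is never
  truncated.
* The record-card separator is fixed at 39 hyphens; adjacent cards in a
  listing share their separator line.
* The rupture-risk criterion itself is external to this package; the
  case schema stores its scalar output (`attach_risk_score`, finite
  values only). The demonstration attaches a seeded uniform stand-in
  score and labels it as such.
* Demonstration problem sizes: round-trip audits use 50 payloads per
  format in the acceptance script and 200 per format in the test suite;
  oracle-equivalence checks use stores of ≤ 100 entities. These sizes
  exercise every code path while keeping the default run fast.

## Known limitations

Single-process embedded storage only (no client/server mode,
transactions beyond SQLite's defaults, or schema migration); the QL
subset has no joins, ordering or inequality predicates; mesh repair and
geometric measures (centerlines, sac volume) are out of scope —
`TriMesh` is a faithful container, not a geometry-processing toolkit;
eUtils API keys, rate limiting and history sessions are not implemented.
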