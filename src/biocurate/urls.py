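"""Structured URL interfaces to remote repositories.

Repositories with a fixed URL syntax (NCBI's Entrez eUtils being the
canonical example) translate a standard set of input parameters into
search and retrieve operations.  This module turns :class:`~biocurate.query.Query`
objects into those URLs deterministically, and executes them through a
pluggable :class:`Transport` so the whole framework can run against either
the live services or in-memory fixtures.

Encoding note: Entrez term strings are emitted with literal ``[``, ``]``
and ``+`` separators (spaces inside values become ``+``), the de-facto
form the eUtils endpoints accept and the one users see in their browsers.
"""

from __future__ import annotations

import re
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass
from typing import Callable, Protocol

from .errors import (
    MalformedIdError,
    RetrievalError,
    UnsupportedRepositoryError,
    ValidationError,
)
from .query import (
    ENTREZ_DATABASES,
    SEARCH_FIELDS,
    Query,
    SearchField,
    SearchType,
    TermConnector,
    validate,
)

#: Default endpoint configuration.  Keys are repository names; values are
#: URL bases or templates.  Entrez defaults to the classic http host; the
#: live service now answers on https, so deployments override this in the
#: endpoint config file.
DEFAULT_ENDPOINTS: dict[str, str] = {
    "ENTREZ_BASE": "http://eutils.ncbi.nlm.nih.gov/entrez/eutils",
    "MALA_CARDS": "http://www.malacards.org/search/results/{term}",
    "BIOMODELS_FETCH": "http://www.ebi.ac.uk/biomodels/model/download/{model_id}",
    "BIOMODELS_SEARCH": "http://www.ebi.ac.uk/biomodels/search?query={term}",
}

BIOMODELS_ID_PATTERN = re.compile(r"^BIOMD\d{10}$")


@dataclass(frozen=True)
class StructuredRequest:
    """An absolute URL plus the payload dialect it is expected to return."""

    url: str
    expected_payload: str  # "XML" | "HTML"


class Transport(Protocol):
    """Delivers the raw bytes behind a structured request.

    Implementations raise :class:`RetrievalError` on failure; the library
    core never opens a network connection itself.
    """

    def fetch(self, request: StructuredRequest) -> bytes: ...


class HttpTransport:
    """Live transport over urllib (no retries, no rate limiting)."""

    def __init__(self, timeout: float = 30.0):
        self.timeout = timeout

    def fetch(self, request: StructuredRequest) -> bytes:
        try:
            with urllib.request.urlopen(request.url, timeout=self.timeout) as resp:
                status = getattr(resp, "status", 200)
                if status >= 400:
                    raise RetrievalError(request.url, f"HTTP status {status}")
                payload = resp.read()
        except urllib.error.URLError as exc:  # DNS, refused, HTTP errors
            raise RetrievalError(request.url, str(exc)) from exc
        if not payload:
            raise RetrievalError(request.url, "empty payload")
        return payload


def _check_valid(query: Query) -> None:
    violations = validate(query)
    if violations:
        raise ValidationError(violations)


def _entrez_term_string(query: Query) -> str:
    """Render the esearch ``term=`` value: field constraints first, then
    free-text terms joined by the query's logical connector."""
    parts = [f"{value}[{sf.tag}]" for sf, value in query.field_constraints]
    connector = f"+{query.term_connector.value}+"
    terms = [t.replace(" ", "+") for t in query.terms]
    if terms:
        parts.append(connector.join(terms))
    return "+".join(parts)


def build_entrez_url(
    query: Query, base: str | None = None, endpoints: dict[str, str] | None = None
) -> StructuredRequest:
    """Translate a query into an Entrez eUtils URL.

    FETCH queries map onto ``efetch.fcgi`` (comma-joined ids, XML records);
    SEARCH queries map onto ``esearch.fcgi`` with ``rettype=uilist`` so the
    response is an identifier list.  Parameter order is fixed
    (db, id|term, retmode, rettype) and the result is deterministic for
    equal queries.
    """
    _check_valid(query)
    if query.database not in ENTREZ_DATABASES:
        raise UnsupportedRepositoryError(
            f"{query.database} is not an Entrez repository"
        )
    cfg = {**DEFAULT_ENDPOINTS, **(endpoints or {})}
    base = base or cfg["ENTREZ_BASE"]
    db = query.database.lower()
    if query.search_type is SearchType.FETCH:
        url = f"{base}/efetch.fcgi?db={db}&id={','.join(query.ids)}&retmode=xml"
    else:
        url = (
            f"{base}/esearch.fcgi?db={db}&term={_entrez_term_string(query)}"
            "&retmode=xml&rettype=uilist"
        )
    return StructuredRequest(url=url, expected_payload="XML")


def parse_entrez_url(request: StructuredRequest | str) -> Query:
    """Recover the query encoded in a generated Entrez URL.

    Inverse of :func:`build_entrez_url` over queries whose terms and field
    values contain no spaces (space and the ``+`` separator share a wire
    encoding, so the inversion is only defined on that subset).
    """
    url = request.url if isinstance(request, StructuredRequest) else request
    parsed = urllib.parse.urlparse(url)
    params = dict(
        pair.split("=", 1) for pair in parsed.query.split("&") if "=" in pair
    )
    db = params["db"].upper()
    if parsed.path.endswith("efetch.fcgi"):
        return Query(
            database=db,
            search_type=SearchType.FETCH,
            ids=tuple(params["id"].split(",")),
        )
    tokens = params["term"].split("+")
    fields: list[tuple[SearchField, str]] = []
    terms: list[str] = []
    connector = TermConnector.AND
    tag_to_field = {f.tag: f for f in SEARCH_FIELDS.values()}
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        m = re.fullmatch(r"(.*)\[([^\]]+)\]", tok)
        if m and not terms:
            tag = m.group(2)
            fields.append((tag_to_field.get(tag, SearchField(tag.upper(), tag)), m.group(1)))
        elif tok in ("AND", "OR") and terms:
            connector = TermConnector(tok)
        else:
            terms.append(tok)
        i += 1
    return Query(
        database=db,
        search_type=SearchType.SEARCH,
        terms=tuple(terms),
        field_constraints=tuple(fields),
        term_connector=connector,
    )


def build_malacards_url(
    query: Query, endpoints: dict[str, str] | None = None
) -> StructuredRequest:
    """Build the MalaCards disease-search URL for the query's first term.

    The endpoint template is configuration (the compendium does not publish
    a stable machine API); the default searches by result-page path.  The
    result page links each hit as a relative ``/card/<slug>?search=<term>``
    anchor, which the HTML parser consumes.
    """
    if not query.terms:
        raise ValidationError(["MalaCards search requires at least one term"])
    cfg = {**DEFAULT_ENDPOINTS, **(endpoints or {})}
    term = urllib.parse.quote_plus(query.terms[0])
    return StructuredRequest(
        url=cfg["MALA_CARDS"].format(term=term), expected_payload="HTML"
    )


def build_biomodels_request(
    query: Query, endpoints: dict[str, str] | None = None
) -> StructuredRequest:
    """Build a request for a model's XML record (by id) or a model search
    (by term).  Model identifiers must match ``BIOMD`` + 10 digits."""
    cfg = {**DEFAULT_ENDPOINTS, **(endpoints or {})}
    if query.ids:
        model_id = query.ids[0]
        if not BIOMODELS_ID_PATTERN.match(model_id):
            raise MalformedIdError(
                f"{model_id!r} does not match the BIOMD+10-digit id format"
            )
        return StructuredRequest(
            url=cfg["BIOMODELS_FETCH"].format(model_id=model_id),
            expected_payload="XML",
        )
    if query.terms:
        term = urllib.parse.quote_plus(query.terms[0])
        return StructuredRequest(
            url=cfg["BIOMODELS_SEARCH"].format(term=term), expected_payload="XML"
        )
    raise ValidationError(["Biomodels query requires a model id or a search term"])


def execute(request: StructuredRequest, transport: Transport) -> bytes:
    """Run a structured request through a transport, returning the payload
    bytes unmodified.  Transport failures surface as :class:`RetrievalError`
    with the URL attached."""
    payload = transport.fetch(request)
    if not payload:
        raise RetrievalError(request.url, "empty payload")
    return payload


def load_endpoint_config(path) -> dict[str, str]:
    """Read endpoint overrides from a plain-text config file.

    Format: one ``KEY = value`` pair per line; blank lines and ``#``
    comments ignored.  Keys are repository/endpoint names as in
    :data:`DEFAULT_ENDPOINTS`.
    """
    overrides: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed endpoint config line: {line!r}")
            key, value = line.split("=", 1)
            overrides[key.strip()] = value.strip()
    return overrides
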