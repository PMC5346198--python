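"""Query objects and the controlled vocabularies they draw from.

A :class:`Query` captures a user's search intent against one repository:
either a term/field search (``SearchType.SEARCH``) or a fetch of known
record identifiers (``SearchType.FETCH``).  The repository catalogue
(:class:`DatabaseId` entries) and the advanced-search field vocabulary
(:class:`SearchField`) are plain data and user-extensible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable


class SearchType(enum.Enum):
    """What a query asks a repository to do."""

    SEARCH = "search"   # terms/fields in, identifier list out
    FETCH = "fetch"     # identifiers in, full records out


class TermConnector(enum.Enum):
    """Logical relation applied between free-text search terms."""

    AND = "AND"
    OR = "OR"


class AccessMode(enum.Enum):
    """How a repository is reached."""

    STRUCTURED_URL = "structured-url"           # remote, fixed URL syntax
    LOCAL_STRUCTURED = "local-structured-information"  # local files/tables


@dataclass(frozen=True)
class DatabaseId:
    """A repository catalogue entry.

    ``name`` is the symbolic name used in code, ``wire_name`` the token that
    appears inside URLs (``db=pubmed``), and ``access`` how the repository
    is reached.
    """

    name: str
    wire_name: str
    access: AccessMode


@dataclass(frozen=True)
class SearchField:
    """An advanced-search field with its Entrez-style tag."""

    name: str
    tag: str

    def __post_init__(self) -> None:
        if not self.tag:
            raise ValueError(f"search field {self.name!r} has an empty tag")


class DatabaseRepository:
    """Expandable catalogue of repositories known to the framework.

    Each entry may carry configuration (endpoint templates, base URLs)
    consumed by the URL interfaces.
    """

    def __init__(self) -> None:
        self._entries: dict[str, DatabaseId] = {}
        self.config: dict[str, str] = {}

    def register(self, entry: DatabaseId) -> DatabaseId:
        for existing in self._entries.values():
            if existing.wire_name == entry.wire_name and existing.name != entry.name:
                raise ValueError(
                    f"wire name {entry.wire_name!r} already registered "
                    f"for {existing.name}"
                )
        self._entries[entry.name] = entry
        return entry

    def get(self, name: str) -> DatabaseId:
        try:
            return self._entries[name]
        except KeyError:
            raise KeyError(f"unknown repository {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def names(self) -> list[str]:
        return list(self._entries)


def default_repository() -> DatabaseRepository:
    """The catalogue the framework ships with."""
    repo = DatabaseRepository()
    repo.register(DatabaseId("PUBMED", "pubmed", AccessMode.STRUCTURED_URL))
    repo.register(DatabaseId("PMC", "pmc", AccessMode.STRUCTURED_URL))
    repo.register(DatabaseId("MALA_CARDS", "malacards", AccessMode.STRUCTURED_URL))
    repo.register(DatabaseId("BIOMODELS", "biomodels", AccessMode.STRUCTURED_URL))
    repo.register(DatabaseId("ANEURISK_LOCAL", "aneurisk", AccessMode.LOCAL_STRUCTURED))
    return repo


#: Entrez repositories (wire names accepted by eUtils).
ENTREZ_DATABASES = frozenset({"PUBMED", "PMC"})

#: Shipped advanced-search vocabulary.  The mapping is plain data; callers
#: may construct additional :class:`SearchField` values freely.
JOURNAL = SearchField("JOURNAL", "journal")
PUBLICATION_DATA = SearchField("PUBLICATION_DATA", "pdat")
AUTHOR = SearchField("AUTHOR", "au")
TITLE = SearchField("TITLE", "ti")

SEARCH_FIELDS: dict[str, SearchField] = {
    f.name: f for f in (JOURNAL, PUBLICATION_DATA, AUTHOR, TITLE)
}


@dataclass(frozen=True)
class Query:
    """A repository query with value semantics.

    Instances are immutable; the ``add_*`` helpers return new queries, so
    building a query reads like the fluent style common in ORM front ends
    while equality stays structural.
    """

    database: str
    search_type: SearchType = SearchType.SEARCH
    terms: tuple[str, ...] = ()
    ids: tuple[str, ...] = ()
    field_constraints: tuple[tuple[SearchField, str], ...] = ()
    term_connector: TermConnector = TermConnector.AND

    def add_term(self, term: str) -> "Query":
        return replace(self, terms=self.terms + (term,))

    def add_id(self, record_id: str) -> "Query":
        return replace(self, ids=self.ids + (record_id,))

    def add_field(self, search_field: SearchField, value: str) -> "Query":
        return replace(
            self, field_constraints=self.field_constraints + ((search_field, value),)
        )

    def remove_term(self, term: str) -> "Query":
        """Drop the last occurrence of ``term`` (no-op if absent)."""
        terms = list(self.terms)
        for i in range(len(terms) - 1, -1, -1):
            if terms[i] == term:
                del terms[i]
                break
        return replace(self, terms=tuple(terms))

    def with_search_type(self, search_type: SearchType) -> "Query":
        return replace(self, search_type=search_type)


def validate(query: Query) -> list[str]:
    """Check a query against the model invariants.

    Returns one human-readable violation per broken rule; an empty list
    means the query is valid.  Never mutates the query.
    """
    violations: list[str] = []
    if query.search_type is SearchType.FETCH:
        if not query.ids:
            violations.append("FETCH query must carry at least one record id")
        if query.terms or query.field_constraints:
            violations.append(
                "FETCH query must not carry search terms or field constraints"
            )
    elif query.search_type is SearchType.SEARCH:
        if not query.terms and not query.field_constraints:
            violations.append(
                "SEARCH query must carry at least one term or field constraint"
            )
    for record_id in query.ids:
        if not record_id:
            violations.append("record ids must be non-empty strings")
            break
    if len(set(query.ids)) != len(query.ids):
        violations.append("record ids must not contain duplicates")
    return violations


def fetch_query(database: str, ids: Iterable[str]) -> Query:
    """Convenience constructor for an identifier fetch."""
    return Query(database=database, search_type=SearchType.FETCH, ids=tuple(ids))


def search_query(
    database: str,
    terms: Iterable[str] = (),
    fields: Iterable[tuple[SearchField, str]] = (),
    connector: TermConnector = TermConnector.AND,
) -> Query:
    """Convenience constructor for a term/field search."""
    return Query(
        database=database,
        search_type=SearchType.SEARCH,
        terms=tuple(terms),
        field_constraints=tuple(fields),
        term_connector=connector,
    )
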