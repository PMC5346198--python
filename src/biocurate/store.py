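"""The Persistent Agent: ORM-style entity persistence over embedded SQLite.

The registered entity schema is mapped onto relational tables — one table
per entity kind (one column per persisted field, primary-keyed on the
kind's key field) and one table per association label (source/target key
pairs with foreign keys into the endpoint tables).  SQLite serves as the
embedded, file-backed database manager: a single-file store with a small
footprint that needs no server process.

Retrieval goes through a deliberately small SQL-like query language::

    SELECT a FROM Article a
    SELECT p FROM Aneurysm p WHERE p.patientID = :patientID

i.e. a single entity kind, an alias, and at most one equality predicate
bound to a named parameter.  Joins are unnecessary because association
traversal is materialised on the returned case objects.
"""

from __future__ import annotations

import json
import re
import sqlite3
from dataclasses import dataclass
from typing import Any, Optional

from .errors import QLSyntaxError, SchemaError, StoreError
from .records import AneurysmCase, Article, Author, BioModel, Disease, case_violations
from .schema import EntityKind, EntitySchema, default_schema

# ---------------------------------------------------------------------------
# Field codecs: how persisted field values cross the relational boundary.

def _encode_value(value: Any) -> Any:
    if isinstance(value, tuple) and all(isinstance(a, Author) for a in value):
        return json.dumps([[a.last_name, a.fore_name] for a in value])
    if isinstance(value, bool):
        return int(value)
    return value


def _decode_value(kind: EntityKind, field_name: str, value: Any) -> Any:
    if value is None:
        return None
    if kind.name == "Article" and field_name == "authors":
        return tuple(Author(last, fore) for last, fore in json.loads(value))
    if kind.name == "Article" and field_name == "year":
        return int(value)
    if kind.name == "Aneurysm" and field_name == "age":
        return int(value)
    if kind.name == "Aneurysm" and field_name == "riskScore":
        return float(value)
    if kind.name == "Model" and field_name == "document":
        return bytes(value)
    return value


def _column_type(kind: EntityKind, field_name: str) -> str:
    if field_name in ("age", "year"):
        return "INTEGER"
    if field_name == "riskScore":
        return "REAL"
    if field_name == "document":
        return "BLOB"
    return "TEXT"


def _assoc_table(label: str) -> str:
    return "assoc_" + re.sub(r"\W", "_", label)


def _entity_table(kind_name: str) -> str:
    return "entity_" + kind_name


# ---------------------------------------------------------------------------
# Query language.

@dataclass(frozen=True)
class Predicate:
    field: str
    parameter: str


@dataclass(frozen=True)
class QueryPlan:
    """A parsed statement: entity kind, alias, optional equality predicate."""

    kind: str
    alias: str
    predicate: Optional[Predicate] = None


_TOKEN = re.compile(r"\S+")


def parse_ql(text: str, schema: EntitySchema | None = None) -> QueryPlan:
    """Parse a statement of the query-language subset into a plan.

    Grammar (keywords case-insensitive, aliases case-sensitive)::

        SELECT <alias> FROM <Kind> <alias> [WHERE <alias>.<field> = :<param>]

    Any deviation raises :class:`QLSyntaxError` carrying the character
    offset of the offending token; unknown kinds and fields are reported
    the same way.
    """
    schema = schema or default_schema()
    tokens = [(m.start(), m.group()) for m in _TOKEN.finditer(text)]
    pos = 0

    def take(description: str) -> tuple[int, str]:
        nonlocal pos
        if pos >= len(tokens):
            raise QLSyntaxError(f"expected {description}", len(text))
        token = tokens[pos]
        pos += 1
        return token

    def keyword(word: str) -> None:
        offset, token = take(f"keyword {word}")
        if token.upper() != word:
            raise QLSyntaxError(f"expected keyword {word}, got {token!r}", offset)

    ident_re = re.compile(r"^[A-Za-z_]\w*$")

    keyword("SELECT")
    alias_offset, select_alias = take("alias")
    if not ident_re.match(select_alias):
        raise QLSyntaxError(f"invalid alias {select_alias!r}", alias_offset)
    keyword("FROM")
    kind_offset, kind_name = take("entity kind")
    from_alias_offset, from_alias = take("alias")
    if not ident_re.match(from_alias):
        raise QLSyntaxError(f"invalid alias {from_alias!r}", from_alias_offset)
    if select_alias != from_alias:
        raise QLSyntaxError(
            f"SELECT alias {select_alias!r} does not match FROM alias "
            f"{from_alias!r}",
            from_alias_offset,
        )
    if kind_name not in schema.kinds:
        raise QLSyntaxError(f"unknown entity kind {kind_name!r}", kind_offset)
    kind = schema.kinds[kind_name]

    predicate = None
    if pos < len(tokens):
        keyword("WHERE")
        path_offset, path = take("predicate")
        m = re.match(r"^([A-Za-z_]\w*)\.([A-Za-z_]\w*)$", path)
        if not m:
            raise QLSyntaxError(f"expected <alias>.<field>, got {path!r}", path_offset)
        if m.group(1) != select_alias:
            raise QLSyntaxError(
                f"predicate alias {m.group(1)!r} does not match {select_alias!r}",
                path_offset,
            )
        field_name = m.group(2)
        if field_name not in dict(kind.fields):
            raise QLSyntaxError(
                f"unknown field {field_name!r} on {kind_name}", path_offset
            )
        eq_offset, eq = take("'='")
        if eq != "=":
            raise QLSyntaxError(f"expected '=', got {eq!r}", eq_offset)
        param_offset, param = take("named parameter")
        if not re.match(r"^:[A-Za-z_]\w*$", param):
            raise QLSyntaxError(
                f"expected named parameter ':name', got {param!r}", param_offset
            )
        predicate = Predicate(field=field_name, parameter=param[1:])
    if pos < len(tokens):
        offset, token = tokens[pos]
        raise QLSyntaxError(f"unexpected trailing token {token!r}", offset)
    return QueryPlan(kind=kind_name, alias=select_alias, predicate=predicate)


# ---------------------------------------------------------------------------
# The store.

class EntityStore:
    """Embedded relational image of an entity schema.

    Parameters
    ----------
    path:
        SQLite database file, or ``":memory:"`` for a transient store.
    schema:
        The entity schema to map; defaults to the demonstration schema.
    """

    def __init__(self, path: str = ":memory:", schema: EntitySchema | None = None):
        self.path = str(path)
        self.schema = schema or default_schema()
        self._conn: sqlite3.Connection | None = None
        self.open()

    # -- lifecycle ---------------------------------------------------------

    def open(self) -> "EntityStore":
        if self._conn is None:
            self._conn = sqlite3.connect(self.path)
            self._conn.execute("PRAGMA foreign_keys = ON")
            self._create_tables()
        return self

    def close(self) -> None:
        if self._conn is not None:
            self._conn.commit()
            self._conn.close()
            self._conn = None

    def __enter__(self) -> "EntityStore":
        return self.open()

    def __exit__(self, *exc) -> None:
        self.close()

    @property
    def connection(self) -> sqlite3.Connection:
        if self._conn is None:
            raise StoreError("store is closed")
        return self._conn

    def _create_tables(self) -> None:
        cur = self.connection
        for kind in self.schema.kinds.values():
            columns = ", ".join(
                f'"{field}" {_column_type(kind, field)}'
                + (" PRIMARY KEY" if field == kind.key_field else "")
                for field, _ in kind.fields
            )
            cur.execute(f'CREATE TABLE IF NOT EXISTS "{_entity_table(kind.name)}" ({columns})')
        for label, (source, target) in self.schema.labels.items():
            source_kind = self.schema.kinds[source]
            target_kind = self.schema.kinds[target]
            cur.execute(
                f'CREATE TABLE IF NOT EXISTS "{_assoc_table(label)}" ('
                "source_key TEXT NOT NULL "
                f'REFERENCES "{_entity_table(source)}"("{source_kind.key_field}"), '
                "target_key TEXT NOT NULL "
                f'REFERENCES "{_entity_table(target)}"("{target_kind.key_field}"), '
                "UNIQUE(source_key, target_key))"
            )
        cur.commit()

    # -- persistence -------------------------------------------------------

    def persist(self, entity) -> str:
        """Durably store an entity (upsert on its key) and, transitively,
        every entity reachable through its associations.  Returns the
        stored key."""
        conn = self.connection
        kind = self.schema.kind_for(entity)
        self._check_entity(kind, entity)
        key = self._upsert(kind, entity)
        for label, targets in getattr(entity, "associations", {}).items():
            if label not in self.schema.labels:
                raise SchemaError(f"unknown association label {label!r}")
            source_name, target_name = self.schema.labels[label]
            if source_name != kind.name:
                raise SchemaError(
                    f"label {label!r} does not originate from {kind.name}"
                )
            for target in targets:
                target_kind = self.schema.kind_for(target)
                if target_kind.name != target_name:
                    raise SchemaError(
                        f"label {label!r} expects {target_name} targets"
                    )
                target_key = self._upsert(target_kind, target)
                conn.execute(
                    f'INSERT OR IGNORE INTO "{_assoc_table(label)}" '
                    "(source_key, target_key) VALUES (?, ?)",
                    (key, target_key),
                )
        conn.commit()
        return key

    def _check_entity(self, kind: EntityKind, entity) -> None:
        if isinstance(entity, AneurysmCase):
            violations = case_violations(
                entity.sex, entity.age, entity.aneurysm_type, entity.status
            )
            if violations:
                raise StoreError("; ".join(violations))

    def _upsert(self, kind: EntityKind, entity) -> str:
        fields = [f for f, _ in kind.fields]
        values = [
            _encode_value(getattr(entity, attr)) for _, attr in kind.fields
        ]
        placeholders = ", ".join("?" for _ in fields)
        columns = ", ".join(f'"{f}"' for f in fields)
        updates = ", ".join(
            f'"{f}" = excluded."{f}"' for f in fields if f != kind.key_field
        )
        self.connection.execute(
            f'INSERT INTO "{_entity_table(kind.name)}" ({columns}) '
            f"VALUES ({placeholders}) "
            f'ON CONFLICT("{kind.key_field}") DO UPDATE SET {updates}',
            values,
        )
        return kind.key_of(entity)

    # -- retrieval ---------------------------------------------------------

    def run_query(
        self, plan: QueryPlan, params: dict | None = None
    ) -> list:
        """Execute a parsed plan, returning entities in insertion order.

        Case results come back with their associated articles, diseases
        and models materialised on ``case.associations``.
        """
        params = params or {}
        kind = self.schema.kind_named(plan.kind)
        sql = f'SELECT * FROM "{_entity_table(kind.name)}"'
        args: list = []
        if plan.predicate is not None:
            if plan.predicate.parameter not in params:
                raise StoreError(
                    f"unbound parameter :{plan.predicate.parameter}"
                )
            sql += f' WHERE "{plan.predicate.field}" = ?'
            args.append(params[plan.predicate.parameter])
        sql += " ORDER BY rowid"
        rows = self.connection.execute(sql, args).fetchall()
        return [self._materialise(kind, row) for row in rows]

    def query(self, statement: str, params: dict | None = None) -> list:
        """Parse and run an SQL-like statement in one step."""
        return self.run_query(parse_ql(statement, self.schema), params)

    def _materialise(self, kind: EntityKind, row) -> Any:
        attrs = {
            attr: _decode_value(kind, field, value)
            for (field, attr), value in zip(kind.fields, row)
        }
        entity = kind.cls(**attrs)
        if isinstance(entity, AneurysmCase):
            self._load_associations(kind, entity)
        return entity

    def _load_associations(self, kind: EntityKind, case: AneurysmCase) -> None:
        key = kind.key_of(case)
        for label, (source, target) in self.schema.labels.items():
            if source != kind.name:
                continue
            target_kind = self.schema.kinds[target]
            rows = self.connection.execute(
                f'SELECT e.* FROM "{_assoc_table(label)}" a '
                f'JOIN "{_entity_table(target)}" e '
                f'ON e."{target_kind.key_field}" = a.target_key '
                "WHERE a.source_key = ? ORDER BY e.rowid",
                (key,),
            ).fetchall()
            if rows:
                case.associations[label] = [
                    self._materialise(target_kind, row) for row in rows
                ]

    # -- inspection --------------------------------------------------------

    def count(self, kind_name: str) -> int:
        """Row count of an entity kind's table."""
        kind = self.schema.kind_named(kind_name)
        (n,) = self.connection.execute(
            f'SELECT COUNT(*) FROM "{_entity_table(kind.name)}"'
        ).fetchone()
        return n

    def check_integrity(self) -> list[str]:
        """Direct-table referential-integrity audit: association rows whose
        endpoints are missing from the entity tables.  Empty list = sound."""
        problems: list[str] = []
        for label, (source, target) in self.schema.labels.items():
            for side, kind_name in (("source", source), ("target", target)):
                kind = self.schema.kinds[kind_name]
                rows = self.connection.execute(
                    f'SELECT {side}_key FROM "{_assoc_table(label)}" '
                    f"WHERE {side}_key NOT IN "
                    f'(SELECT "{kind.key_field}" FROM "{_entity_table(kind_name)}")'
                ).fetchall()
                problems.extend(
                    f"{label}: dangling {side} key {row[0]!r}" for row in rows
                )
        return problems


def persist(store: EntityStore, entity) -> str:
    """Module-level convenience mirroring :meth:`EntityStore.persist`."""
    return store.persist(entity)


def run_query(store: EntityStore, plan: QueryPlan, params: dict | None = None) -> list:
    """Module-level convenience mirroring :meth:`EntityStore.run_query`."""
    return store.run_query(plan, params)
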