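"""The user-defined entity schema of the demonstration database.

The hub entity is the clinical :class:`~biocurate.records.AneurysmCase`;
articles, diseases and mathematical models attach to it through labelled
many-to-many associations, and an externally computed rupture-risk scalar
is stored as a case attribute.  The schema — entity kinds, their
persistable fields and the association labels between them — is what the
persistent agent maps onto relational tables.

Entity kinds carry both a Python attribute name and a persisted field
name per column, so the query language can expose the conventional
camel-case field names (``patientID``) over snake-case dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

from .errors import SchemaError
from .records import AneurysmCase, Article, BioModel, Disease, finite_or_error

#: Shipped association labels.
CASE_ARTICLE = "case-article"
CASE_DISEASE = "case-disease"
CASE_MODEL = "case-model"


@dataclass(frozen=True)
class Association:
    """A labelled, directed link between two persisted entities."""

    source_kind: str
    source_key: str
    target_kind: str
    target_key: str
    label: str


@dataclass(frozen=True)
class EntityKind:
    """One registered entity kind.

    ``fields`` maps persisted field names to dataclass attribute names;
    ``key_field`` names the persisted field acting as the primary key.
    """

    name: str
    cls: type
    key_field: str
    fields: tuple[tuple[str, str], ...]

    def attribute_for(self, field_name: str) -> str:
        for persisted, attr in self.fields:
            if persisted == field_name:
                return attr
        raise KeyError(field_name)

    def key_of(self, entity) -> str:
        return str(getattr(entity, self.attribute_for(self.key_field)))


@dataclass
class EntitySchema:
    """Registered entity kinds plus the association labels between them."""

    kinds: dict = dc_field(default_factory=dict)
    labels: dict = dc_field(default_factory=dict)  # label -> (source kind, target kind)

    def register_kind(self, kind: EntityKind) -> EntityKind:
        if kind.name in self.kinds and self.kinds[kind.name] != kind:
            raise SchemaError(f"entity kind {kind.name!r} already registered")
        self.kinds[kind.name] = kind
        return kind

    def register_label(self, label: str, source: str, target: str) -> None:
        endpoints = (source, target)
        if label in self.labels and self.labels[label] != endpoints:
            raise SchemaError(f"association label {label!r} already registered")
        self.labels[label] = endpoints

    def kind_for(self, entity) -> EntityKind:
        for kind in self.kinds.values():
            if isinstance(entity, kind.cls):
                return kind
        raise SchemaError(f"no entity kind registered for {type(entity).__name__}")

    def kind_named(self, name: str) -> EntityKind:
        try:
            return self.kinds[name]
        except KeyError:
            raise SchemaError(f"unknown entity kind {name!r}") from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, EntitySchema):
            return NotImplemented
        return self.kinds == other.kinds and self.labels == other.labels


def default_schema() -> EntitySchema:
    """The demonstration database schema.

    The case kind is registered under the query-language name ``Aneurysm``
    with field ``patientID``, the names its users query it by.
    """
    schema = EntitySchema()
    schema.register_kind(
        EntityKind(
            name="Article",
            cls=Article,
            key_field="pmid",
            fields=(
                ("pmid", "pmid"),
                ("title", "title"),
                ("authors", "authors"),
                ("journal", "journal"),
                ("volume", "volume"),
                ("issue", "issue"),
                ("year", "year"),
                ("doi", "doi"),
                ("abstract", "abstract"),
            ),
        )
    )
    schema.register_kind(
        EntityKind(
            name="Disease",
            cls=Disease,
            key_field="cardLink",
            fields=(("name", "name"), ("cardLink", "card_link")),
        )
    )
    schema.register_kind(
        EntityKind(
            name="Model",
            cls=BioModel,
            key_field="modelId",
            fields=(
                ("modelId", "model_id"),
                ("description", "description"),
                ("document", "document"),
            ),
        )
    )
    schema.register_kind(
        EntityKind(
            name="Aneurysm",
            cls=AneurysmCase,
            key_field="patientID",
            fields=(
                ("patientID", "patient_id"),
                ("sex", "sex"),
                ("age", "age"),
                ("aneurysmType", "aneurysm_type"),
                ("location", "location"),
                ("status", "status"),
                ("geometryRef", "geometry_ref"),
                ("riskScore", "risk_score"),
            ),
        )
    )
    schema.register_label(CASE_ARTICLE, "Aneurysm", "Article")
    schema.register_label(CASE_DISEASE, "Aneurysm", "Disease")
    schema.register_label(CASE_MODEL, "Aneurysm", "Model")
    return schema


def associate(
    case: AneurysmCase, target, label: str, schema: EntitySchema | None = None
) -> AneurysmCase:
    """Attach ``target`` to the case under a relation label.

    The association set per label is unordered and duplicate-free:
    associating the same target twice is a no-op.  The label must be
    declared for the target's kind.
    """
    schema = schema or default_schema()
    if label not in schema.labels:
        raise SchemaError(f"unknown association label {label!r}")
    source_kind_name, target_kind_name = schema.labels[label]
    target_kind = schema.kind_for(target)
    if target_kind.name != target_kind_name:
        raise SchemaError(
            f"label {label!r} links {source_kind_name} to {target_kind_name}, "
            f"not to {target_kind.name}"
        )
    if target is case:
        raise SchemaError("an entity cannot be associated with itself")
    bucket = case.associations.setdefault(label, [])
    key = target_kind.key_of(target)
    if all(target_kind.key_of(existing) != key for existing in bucket):
        bucket.append(target)
    return case


def attach_risk_score(case: AneurysmCase, score: float) -> AneurysmCase:
    """Set the case's rupture-risk scalar (computed externally), replacing
    any prior value.  Non-finite scores are rejected."""
    case.risk_score = finite_or_error(score)
    return case
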