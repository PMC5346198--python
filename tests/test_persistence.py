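"""The persistent agent: mapping, upserts, the query language, durability."""

import numpy as np
import pytest

from biocurate.errors import QLSyntaxError, StoreError
from biocurate.fixtures import (
    random_article,
    random_biomodel,
    random_case,
    random_disease,
)
from biocurate.records import BioModel
from biocurate.schema import CASE_ARTICLE, associate
from biocurate.store import EntityStore, parse_ql, QueryPlan


@pytest.fixture
def store():
    with EntityStore(":memory:") as s:
        yield s


class TestPersist:
    def test_two_articles_two_rows(self, store, demo_articles):
        for article in demo_articles:
            store.persist(article)
        assert store.count("Article") == 2

    def test_persisting_same_article_twice_is_an_upsert(self, store, demo_articles):
        store.persist(demo_articles[0])
        store.persist(demo_articles[0])
        assert store.count("Article") == 1

    def test_upsert_updates_fields(self, store, demo_articles):
        import dataclasses

        store.persist(demo_articles[0])
        updated = dataclasses.replace(demo_articles[0], year=2014)
        store.persist(updated)
        (got,) = store.query("SELECT a FROM Article a")
        assert got.year == 2014 and store.count("Article") == 1

    def test_cascade_persists_associated_articles(self, store, demo_articles,
                                                  demo_cases):
        case = demo_cases[0]
        associate(case, demo_articles[0], CASE_ARTICLE)
        store.persist(case)
        assert store.count("Article") == 1
        assert store.count("Aneurysm") == 1

    def test_closed_store_rejects_operations(self, store_path, demo_articles):
        store = EntityStore(store_path)
        store.close()
        with pytest.raises(StoreError, match="closed"):
            store.persist(demo_articles[0])

    def test_invariant_violating_case_rejected(self, store, demo_cases):
        case = demo_cases[0]
        case.status = "X"  # mutated after construction
        with pytest.raises(StoreError, match="status"):
            store.persist(case)

    def test_referential_integrity_after_persist_sequences(self, store,
                                                           demo_articles,
                                                           demo_cases):
        for case in demo_cases:
            for article in demo_articles:
                associate(case, article, CASE_ARTICLE)
            store.persist(case)
        store.persist(demo_articles[0])  # re-persist an association target
        assert store.check_integrity() == []


class TestParseQl:
    def test_bare_select(self):
        plan = parse_ql("SELECT a FROM Article a")
        assert plan == QueryPlan(kind="Article", alias="a", predicate=None)

    def test_select_with_equality_predicate(self):
        plan = parse_ql("SELECT p FROM Aneurysm p WHERE p.patientID = :patientID")
        assert plan.kind == "Aneurysm"
        assert plan.predicate.field == "patientID"
        assert plan.predicate.parameter == "patientID"

    def test_keywords_are_case_insensitive(self):
        assert parse_ql("select a from Article a").kind == "Article"

    @pytest.mark.parametrize(
        "statement, fragment",
        [
            ("SELECT x FROM Article a", "alias"),
            ("SELECT a FROM Nothing a", "unknown entity kind"),
            ("SELECT a FROM Article a WHERE a.nope = :x", "unknown field"),
            ("SELECT a FROM Article a WHERE b.pmid = :x", "alias"),
            ("SELECT a FROM Article a WHERE a.pmid := x", "'='"),
            ("SELECT a FROM Article a WHERE a.pmid = x", "named parameter"),
            ("SELECT a FROM Article a extra", "WHERE"),
            ("SELECT a", "expected"),
        ],
    )
    def test_grammar_violations_raise_with_offset(self, statement, fragment):
        with pytest.raises(QLSyntaxError, match=fragment) as exc:
            parse_ql(statement)
        assert 0 <= exc.value.offset <= len(statement)


class TestRunQuery:
    def test_all_articles_returned_without_predicate(self, store, demo_articles):
        for article in demo_articles:
            store.persist(article)
        results = store.query("SELECT a FROM Article a")
        assert results == demo_articles  # insertion order

    def test_absent_patient_gives_empty_list(self, store):
        results = store.query(
            "SELECT p FROM Aneurysm p WHERE p.patientID = :patientID",
            {"patientID": "CD0985674"},
        )
        assert results == []

    def test_unbound_parameter_is_an_error(self, store):
        with pytest.raises(StoreError, match="unbound"):
            store.query("SELECT p FROM Aneurysm p WHERE p.patientID = :patientID")

    def test_predicate_matches_exactly_one_random_case(self, store):
        rng = np.random.default_rng(42)
        cases, seen = [], set()
        while len(cases) < 30:
            case = random_case(rng)
            if case.patient_id not in seen:
                seen.add(case.patient_id)
                cases.append(case)
                store.persist(case)
        target = cases[17]
        results = store.query(
            "SELECT p FROM Aneurysm p WHERE p.patientID = :patientID",
            {"patientID": target.patient_id},
        )
        assert results == [target]

    def test_predicate_equals_linear_scan_oracle(self, store):
        """Filtered retrieval must coincide with a brute-force scan of the
        unfiltered result for every queried value."""
        rng = np.random.default_rng(7)
        for _ in range(60):
            store.persist(random_case(rng))  # duplicate keys upsert
        everything = store.query("SELECT p FROM Aneurysm p")
        for status in ("U", "R"):
            filtered = store.query(
                "SELECT p FROM Aneurysm p WHERE p.status = :s", {"s": status}
            )
            assert filtered == [c for c in everything if c.status == status]

    def test_string_comparison_is_case_sensitive(self, store, demo_cases):
        store.persist(demo_cases[0])
        assert store.query(
            "SELECT p FROM Aneurysm p WHERE p.patientID = :id", {"id": "c0004"}
        ) == []


class TestRoundTripAndDurability:
    @pytest.mark.parametrize(
        "maker, kind",
        [
            (random_article, "Article"),
            (random_disease, "Disease"),
            (random_biomodel, "Model"),
            (random_case, "Aneurysm"),
        ],
    )
    def test_every_kind_round_trips_field_for_field(self, store_path, maker, kind):
        rng = np.random.default_rng(3)
        entities, seen = [], set()
        while len(entities) < 10:
            entity = maker(rng)
            schema_kind = EntityStore(":memory:").schema.kind_for(entity)
            key = schema_kind.key_of(entity)
            if key not in seen:
                seen.add(key)
                entities.append(entity)
        with EntityStore(store_path) as store:
            for entity in entities:
                store.persist(entity)
        with EntityStore(store_path) as store:  # survives close/reopen
            alias = kind[0].lower()
            reloaded = store.query(f"SELECT {alias} FROM {kind} {alias}")
        assert reloaded == entities

    def test_model_document_payload_survives(self, store_path):
        model = BioModel(
            model_id="BIOMD0000000058", description="calcium", document=b"<sbml/>"
        )
        with EntityStore(store_path) as store:
            store.persist(model)
        with EntityStore(store_path) as store:
            (got,) = store.query("SELECT m FROM Model m")
        assert got.document == b"<sbml/>"
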