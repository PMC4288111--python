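"""Repository schema, statement propagation, guards, queries, round trips."""

import random
import sqlite3

import pytest

from ontoregistry import metamodel as mm
from ontoregistry import store as S
from ontoregistry.exceptions import (
    ContradictoryTypingError,
    GuardViolationError,
    NameCollisionError,
    SchemaError,
    UnknownResourceError,
)
from ontoregistry.namespaces import (
    OWL_CLASS,
    OWL_DATATYPE_PROPERTY,
    OWL_IMPORTS,
    OWL_OBJECT_PROPERTY,
    OWL_ONTOLOGY,
    RDF_TYPE,
    RDFS_DOMAIN,
    RDFS_RANGE,
    RDFS_SUBCLASSOF,
    XSD_NS,
)
from ontoregistry.owl_core import Literal, Statement, StatementSet

NS = "http://example.org/app#"


def st(s, p, o, ns=NS):
    return Statement(s, p, o, ns)


def random_statement_pool(rng, ns=NS, n_classes=10, n_props=5, n_insts=40):
    pool = []
    classes = [f"{ns}C{i}" for i in range(n_classes)]
    props = [f"{ns}p{i}" for i in range(n_props)]
    for c in classes:
        pool.append(st(c, RDF_TYPE, OWL_CLASS, ns))
    for i, c in enumerate(classes[1:], 1):
        pool.append(st(c, RDFS_SUBCLASSOF, classes[rng.randrange(i)], ns))
    for p in props:
        pool.append(st(p, RDF_TYPE, OWL_DATATYPE_PROPERTY, ns))
        pool.append(st(p, RDFS_DOMAIN, rng.choice(classes), ns))
        pool.append(
            st(p, RDFS_RANGE, XSD_NS + rng.choice(["integer", "string"]), ns)
        )
    for i in range(n_insts):
        inst = f"{ns}i{i}"
        pool.append(st(inst, RDF_TYPE, rng.choice(classes), ns))
        pool.append(
            st(inst, rng.choice(props), Literal(str(rng.randrange(100)), "integer"), ns)
        )
    return pool


class TestInit:
    def test_fresh_repository_holds_the_metamodel(self, repo):
        live = repo.one("SELECT COUNT(*) FROM statements WHERE deleted = 0")[0]
        assert live == len(mm.metamodel_statements())

    def test_reopen_is_noop(self, tmp_path):
        path = str(tmp_path / "r.db")
        first = S.init_repository(path)
        count = S.physical_row_count(first)
        first.close()
        second = S.init_repository(path)
        assert S.physical_row_count(second) == count
        second.close()

    @pytest.mark.parametrize("table", ["statements", "classes", "values_integer",
                                       "hierarchy_index", "meta"])
    def test_corrupted_schema_detected(self, tmp_path, table):
        path = str(tmp_path / "r.db")
        S.init_repository(path).close()
        raw = sqlite3.connect(path)
        raw.execute(f"DROP TABLE {table}")
        raw.commit()
        raw.close()
        with pytest.raises(SchemaError, match=table):
            S.init_repository(path)


class TestAssertRetract:
    def test_class_assertion_creates_resource_and_class_row(self, repo):
        effect = S.assert_statement(repo, st(NS + "C", RDF_TYPE, OWL_CLASS))
        assert effect.inserted.get("classes") == 1
        assert effect.inserted.get("statements") == 1
        rid = repo.resource_id(NS + "C")
        assert repo.one(
            "SELECT deleted FROM classes WHERE resource_id = ?", rid
        )[0] == 0

    def test_duplicate_assert_is_noop(self, repo):
        s = st(NS + "C", RDF_TYPE, OWL_CLASS)
        S.assert_statement(repo, s)
        assert S.assert_statement(repo, s).is_noop

    def test_contradictory_typing_leaves_statements_unchanged(self, repo):
        S.assert_statement(repo, st(NS + "x", RDF_TYPE, OWL_CLASS))
        before = repo.one("SELECT COUNT(*) FROM statements")[0]
        with pytest.raises(ContradictoryTypingError):
            S.assert_statement(repo, st(NS + "x", RDF_TYPE, OWL_DATATYPE_PROPERTY))
        assert repo.one("SELECT COUNT(*) FROM statements")[0] == before

    def test_assert_then_retract_restores_live_content(self, repo):
        before_state = S.structural_state(repo)
        before_rows = S.physical_row_count(repo)
        s = st(NS + "C", RDF_TYPE, OWL_CLASS)
        S.assert_statement(repo, s)
        S.retract_statement(repo, s)
        assert S.structural_state(repo) == before_state
        assert S.physical_row_count(repo) > before_rows  # soft delete

    def test_retract_class_with_live_instances_refused(self, repo):
        S.assert_statement(repo, st(NS + "C", RDF_TYPE, OWL_CLASS))
        S.assert_statement(repo, st(NS + "i", RDF_TYPE, NS + "C"))
        before = S.structural_state(repo)
        with pytest.raises(GuardViolationError):
            S.retract_statement(repo, st(NS + "C", RDF_TYPE, OWL_CLASS))
        assert S.structural_state(repo) == before

    def test_retract_property_with_live_values_refused(self, repo):
        S.assert_statement(repo, st(NS + "p", RDF_TYPE, OWL_DATATYPE_PROPERTY))
        S.assert_statement(repo, st(NS + "i", NS + "p", Literal("7", "integer")))
        with pytest.raises(GuardViolationError):
            S.retract_statement(repo, st(NS + "p", RDF_TYPE, OWL_DATATYPE_PROPERTY))

    def test_undeclared_range_defaults_to_string_with_warning(self, repo):
        S.assert_statement(repo, st(NS + "p", RDF_TYPE, OWL_DATATYPE_PROPERTY))
        effect = S.assert_statement(
            repo, st(NS + "i", NS + "p", Literal("5", "integer"))
        )
        assert effect.warnings
        assert effect.inserted.get("values_string") == 1

    def test_monotone_resource_ids(self, repo):
        ids = []
        for name in ("a", "b", "c"):
            S.assert_statement(repo, st(NS + name, RDF_TYPE, OWL_CLASS))
            ids.append(repo.resource_id(NS + name))
        assert ids == sorted(ids)
        S.retract_statement(repo, st(NS + "c", RDF_TYPE, OWL_CLASS))
        S.assert_statement(repo, st(NS + "d", RDF_TYPE, OWL_CLASS))
        assert repo.resource_id(NS + "d") > ids[-1]

    def test_random_interleavings_match_replay_and_rebuild(self, repo):
        """Live content equals a replay of the net statements, and the
        incrementally maintained tables equal a from-scratch rebuild."""
        rng = random.Random(17)
        pool = random_statement_pool(rng)
        live = []
        rows = S.physical_row_count(repo)
        for s in rng.sample(pool, len(pool)):
            S.assert_statement(repo, s)
            live.append(s)
            if live and rng.random() < 0.35:
                victim = rng.choice(live)
                try:
                    S.retract_statement(repo, victim)
                    live.remove(victim)
                except GuardViolationError:
                    pass
            new_rows = S.physical_row_count(repo)
            assert new_rows >= rows
            rows = new_rows
        assert S.structural_state(repo) == S.rebuild_structural(repo)
        replay = S.init_repository()
        for s in sorted(live, key=Statement.sort_key):
            S.assert_statement(replay, s)
        live_keys = {
            k: v
            for k, v in S.structural_state(repo).items()
            if k not in ("resources",)
        }
        # replayed repository has different resource ids; compare by IRI
        def named_state(r):
            out = {}
            iri = {i: r.one("SELECT iri FROM resources WHERE id=?", i)[0]
                   for (i,) in r.q("SELECT id FROM resources")}
            state = S.structural_state(r)
            out["classes"] = {iri[c] for c in state["classes"]}
            out["instances"] = {(iri[a], iri[b]) for a, b in state["instances"]}
            out["values"] = {
                (t, iri[i], iri[p], v) for t, i, p, v in state["values"]
            }
            return out

        assert named_state(repo) == named_state(replay)


class TestTypedValuePlacement:
    def test_value_lands_in_range_table_regardless_of_order(self, repo):
        # value asserted before the range declaration: migrated on declare
        S.assert_statement(repo, st(NS + "p", RDF_TYPE, OWL_DATATYPE_PROPERTY))
        S.assert_statement(repo, st(NS + "i", NS + "p", Literal("3", "integer")))
        S.assert_statement(repo, st(NS + "p", RDFS_RANGE, XSD_NS + "integer"))
        rid = repo.resource_id(NS + "i")
        pid = repo.resource_id(NS + "p")
        assert S.values_of(repo, rid) == {pid: [("integer", 3)]}
        assert S.structural_state(repo) == S.rebuild_structural(repo)

    def test_zero_placement_violations_after_random_load(self, repo):
        rng = random.Random(23)
        for s in random_statement_pool(rng):
            S.assert_statement(repo, s)
        state = S.structural_state(repo)
        ranges = {}
        for pid, kind, ref in state["ranges"]:
            if kind == "datatype":
                ranges.setdefault(pid, []).append(ref)
        violations = 0
        for tag, i, p, v in state["values"]:
            declared = sorted(ranges.get(p, []))
            expected = declared[0] if declared else "string"
            if tag not in ("resource", expected):
                violations += 1
        assert violations == 0


class TestOntologyOps:
    def test_upload_download_round_trip(self, repo, caps_app):
        S.upload_ontology(repo, caps_app, mode="incremental")
        assert S.download_ontology(repo, caps_app.origin_ns).multiset_equal(caps_app)

    def test_deleted_statements_excluded_from_download(self, repo):
        S.assert_statement(repo, st(NS + "C", RDF_TYPE, OWL_CLASS))
        sset = StatementSet.from_statements(
            [st(NS[:-1], RDF_TYPE, OWL_ONTOLOGY), st(NS + "C", RDF_TYPE, OWL_CLASS)],
            origin_ns=NS,
        )
        S.upload_ontology(repo, sset, mode="incremental")
        S.retract_statement(repo, st(NS + "C", RDF_TYPE, OWL_CLASS))
        assert all(
            s.subject != NS + "C" for s in S.download_ontology(repo, NS)
        )

    def test_unknown_namespace_names_loaded_ones(self, repo):
        with pytest.raises(UnknownResourceError, match="metamodel"):
            S.download_ontology(repo, "http://nowhere/#")

    def test_replace_missing_class_with_instances_refused(self, caps_repo, caps_app):
        from ontoregistry.fixtures import populate_instances

        populate_instances(caps_repo, caps_app.origin_ns, n_cases=2, seed=1)
        from tests.conftest import drop_statement

        mutated = drop_statement(
            caps_app, predicate=RDF_TYPE,
            subject=caps_app.origin_ns + "treatment", obj=OWL_CLASS,
        )
        before = S.structural_state(caps_repo)
        with pytest.raises(GuardViolationError):
            S.upload_ontology(caps_repo, mutated, mode="replace")
        assert S.structural_state(caps_repo) == before

    def test_replace_applies_delta(self, repo):
        base = StatementSet.from_statements(
            [st(NS[:-1], RDF_TYPE, OWL_ONTOLOGY),
             st(NS + "A", RDF_TYPE, OWL_CLASS),
             st(NS + "B", RDF_TYPE, OWL_CLASS)],
            origin_ns=NS,
        )
        S.upload_ontology(repo, base, mode="incremental")
        replacement = StatementSet.from_statements(
            [st(NS[:-1], RDF_TYPE, OWL_ONTOLOGY),
             st(NS + "A", RDF_TYPE, OWL_CLASS),
             st(NS + "C", RDF_TYPE, OWL_CLASS)],
            origin_ns=NS,
        )
        S.upload_ontology(repo, replacement, mode="replace")
        assert S.download_ontology(repo, NS).multiset_equal(replacement)

    def test_with_imports_diamond_superset(self, repo):
        def onto(iri, imports=(), extra=()):
            ns = iri + "#"
            statements = [st(iri, RDF_TYPE, OWL_ONTOLOGY, ns)]
            statements += [st(iri, OWL_IMPORTS, i, ns) for i in imports]
            statements += list(extra)
            return StatementSet.from_statements(statements, origin_ns=ns)

        d = onto("http://x/D", extra=[st("http://x/D#c", RDF_TYPE, OWL_CLASS,
                                         "http://x/D#")])
        b = onto("http://x/B", ["http://x/D"])
        c = onto("http://x/C", ["http://x/D"])
        a = onto("http://x/A", ["http://x/B", "http://x/C"])
        resolver = {"http://x/B": b, "http://x/C": c, "http://x/D": d}.__getitem__
        S.upload_ontology(repo, a, with_imports=True, resolver=resolver)
        full = S.download_ontology(repo, "http://x/A#", with_imports=True)
        just_a = S.download_ontology(repo, "http://x/A#")
        assert len(full) > len(just_a)
        triples = set(full.triples())
        assert ("http://x/D#c", RDF_TYPE, OWL_CLASS) in triples
        # import relation stored
        assert ("http://x/A", OWL_IMPORTS, "http://x/B") in triples

    def test_namespace_collision_refused(self, repo):
        one = StatementSet.from_statements(
            [Statement("http://x/one", RDF_TYPE, OWL_ONTOLOGY, "http://x/one#")],
        )
        S.upload_ontology(repo, one, mode="incremental")
        clash = StatementSet.from_statements(
            [Statement("http://x/two", RDF_TYPE, OWL_ONTOLOGY, "http://x/one#")],
            origin_ns="http://x/one#",
        )
        with pytest.raises(NameCollisionError):
            S.upload_ontology(repo, clash, mode="incremental")


class TestQueryApi:
    @pytest.fixture()
    def taxonomy(self, repo):
        # root C0 <- C1 <- C2 chain plus instances
        for c in ("C0", "C1", "C2"):
            S.assert_statement(repo, st(NS + c, RDF_TYPE, OWL_CLASS))
        S.assert_statement(repo, st(NS + "C1", RDFS_SUBCLASSOF, NS + "C0"))
        S.assert_statement(repo, st(NS + "C2", RDFS_SUBCLASSOF, NS + "C1"))
        S.assert_statement(repo, st(NS + "i0", RDF_TYPE, NS + "C0"))
        S.assert_statement(repo, st(NS + "i2", RDF_TYPE, NS + "C2"))
        S.assert_statement(repo, st(NS + "p", RDF_TYPE, OWL_DATATYPE_PROPERTY))
        S.assert_statement(repo, st(NS + "p", RDFS_DOMAIN, NS + "C0"))
        S.assert_statement(repo, st(NS + "p", RDFS_RANGE, XSD_NS + "integer"))
        S.assert_statement(repo, st(NS + "i0", NS + "p", Literal("1", "integer")))
        return {n: repo.resource_id(NS + n) for n in
                ("C0", "C1", "C2", "i0", "i2", "p")}

    def test_direct_vs_transitive_subclasses(self, repo, taxonomy):
        t = taxonomy
        assert S.subclasses_of(repo, t["C0"]) == {t["C1"]}
        assert S.subclasses_of(repo, t["C0"], transitive=True) == {t["C1"], t["C2"]}
        assert S.subclasses_of(repo, t["C2"], transitive=True) == set()

    def test_transitive_instances_span_descendants(self, repo, taxonomy):
        t = taxonomy
        assert S.instances_of(repo, t["C0"]) == {t["i0"]}
        assert S.instances_of(repo, t["C0"], transitive=True) == {t["i0"], t["i2"]}

    def test_property_domain_range_values(self, repo, taxonomy):
        t = taxonomy
        assert S.properties_of(repo, t["C0"]) == {t["p"]}
        assert S.domain_of(repo, t["p"]) == {t["C0"]}
        assert S.range_of(repo, t["p"]) == {("datatype", "integer")}
        assert S.values_of(repo, t["i0"]) == {t["p"]: [("integer", 1)]}

    def test_deleted_or_unknown_id_errors(self, repo, taxonomy):
        with pytest.raises(UnknownResourceError):
            S.subclasses_of(repo, 10**9)

    def test_random_taxonomy_matches_recursive_oracle(self, repo):
        rng = random.Random(9)
        classes = [f"{NS}T{i}" for i in range(120)]
        for c in classes:
            S.assert_statement(repo, st(c, RDF_TYPE, OWL_CLASS))
        for i, c in enumerate(classes[1:], 1):
            S.assert_statement(
                repo, st(c, RDFS_SUBCLASSOF, classes[rng.randrange(i)])
            )
        ids = {c: repo.resource_id(c) for c in classes}

        def recursive(c):
            out = set()
            for d in S.subclasses_of(repo, c):
                out |= {d} | recursive(d)
            return out

        for c in rng.sample(classes, 25):
            assert S.subclasses_of(repo, ids[c], transitive=True) == recursive(
                ids[c]
            )
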