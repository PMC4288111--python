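"""Statement model, serialization round trips, classification, imports."""

import pytest
import rdflib
from hypothesis import given, settings, strategies as st

from ontoregistry import owl_core as oc
from ontoregistry.exceptions import (
    ContradictoryTypingError,
    ImportCycleError,
    ParseError,
    UnresolvableImportError,
    UnsupportedDatatypeError,
    UnsupportedDialectError,
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

EX = "http://example.org/t#"

MINIMAL = """<?xml version="1.0"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:owl="http://www.w3.org/2002/07/owl#">
  <owl:Ontology rdf:about="http://example.org/t"/>
</rdf:RDF>"""

CASE_AGE = """<?xml version="1.0"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:owl="http://www.w3.org/2002/07/owl#"
         xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#">
  <owl:Class rdf:about="http://example.org/t#Case"/>
  <owl:DatatypeProperty rdf:about="http://example.org/t#age">
    <rdfs:domain rdf:resource="http://example.org/t#Case"/>
    <rdfs:range rdf:resource="http://www.w3.org/2001/XMLSchema#integer"/>
  </owl:DatatypeProperty>
</rdf:RDF>"""


def stmt(s, p, o):
    return oc.Statement(s, p, o, EX)


class TestParse:
    def test_minimal_ontology_header(self):
        sset = oc.parse_owl(MINIMAL)
        assert len(sset) == 1
        assert sset.ontology_iri == "http://example.org/t"
        assert sset.imports == []

    def test_class_and_property_document(self):
        sset = oc.parse_owl(CASE_AGE)
        kinds = oc.classify_resources(sset)
        assert kinds[EX + "Case"] is oc.ResourceKind.NAMED_CLASS
        assert kinds[EX + "age"] is oc.ResourceKind.DATATYPE_PROPERTY
        triples = set(sset.triples())
        assert (EX + "age", RDFS_DOMAIN, EX + "Case") in triples
        assert (EX + "age", RDFS_RANGE, XSD_NS + "integer") in triples

    def test_statement_list_matches_independent_parser(self):
        """Our statement extraction agrees with a direct rdflib graph."""
        g = rdflib.Graph()
        g.parse(data=CASE_AGE, format="xml")
        sset = oc.parse_owl(CASE_AGE)
        assert len(sset) == len(g)
        ours = {(s, p, str(o) if not isinstance(o, oc.Literal) else o.lexical)
                for s, p, o in sset.triples()}
        theirs = {(str(s), str(p), str(o)) for s, p, o in g}
        assert ours == theirs

    def test_malformed_document_reports_position(self):
        with pytest.raises(ParseError):
            oc.parse_owl("<rdf:RDF this is not xml")
        with pytest.raises(ParseError):
            oc.parse_owl("@prefix broken", dialect="turtle")

    def test_unsupported_dialect_rejected(self):
        with pytest.raises(UnsupportedDialectError):
            oc.parse_owl(MINIMAL, dialect="n3")

    def test_unsupported_literal_datatype_named(self):
        doc = MINIMAL.replace(
            "</rdf:RDF>",
            '<rdf:Description rdf:about="http://example.org/t#x">'
            '<rdf:value rdf:datatype="http://www.w3.org/2001/XMLSchema#duration"'
            ">P1Y</rdf:value></rdf:Description></rdf:RDF>",
        )
        with pytest.raises(UnsupportedDatatypeError, match="duration"):
            oc.parse_owl(doc)


class TestSerialize:
    @pytest.mark.parametrize("dialect", ["rdfxml", "turtle"])
    def test_round_trip(self, dialect):
        sset = oc.parse_owl(CASE_AGE)
        out = oc.serialize_owl(sset, dialect)
        again = oc.parse_owl(out, dialect)
        assert sset.multiset_equal(again)

    def test_byte_determinism(self):
        sset = oc.parse_owl(CASE_AGE)
        assert oc.serialize_owl(sset) == oc.serialize_owl(sset)
        # reordering the statements must not change the bytes
        reordered = oc.StatementSet.from_statements(
            list(reversed(sset.statements)), origin_ns=sset.origin_ns
        )
        assert oc.serialize_owl(sset) == oc.serialize_owl(reordered)

    def test_unsupported_datatype_rejected_by_literal(self):
        with pytest.raises(UnsupportedDatatypeError, match="gYear"):
            oc.Literal("2001", "gYear")

    def test_blank_nodes_round_trip_modulo_relabeling(self):
        doc = """<?xml version="1.0"?>
        <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
                 xmlns:ex="http://example.org/t#">
          <rdf:Description rdf:about="http://example.org/t#a">
            <ex:linked rdf:nodeID="x"/>
          </rdf:Description>
          <rdf:Description rdf:nodeID="x">
            <ex:name>anonymous</ex:name>
          </rdf:Description>
        </rdf:RDF>"""
        sset = oc.parse_owl(doc)
        assert any(oc.is_blank(s.subject) for s in sset)
        assert sset.multiset_equal(oc.parse_owl(oc.serialize_owl(sset)))


# a small vocabulary for generated statement sets
_subjects = st.sampled_from([EX + n for n in "abcdef"])
_predicates = st.sampled_from(
    [EX + "p1", EX + "p2", "http://www.w3.org/2000/01/rdf-schema#label"]
)
_literals = st.one_of(
    st.builds(oc.Literal, st.text(alphabet="xyz0 9", max_size=6), st.just("string")),
    st.builds(lambda n: oc.Literal(str(n), "integer"), st.integers(-99, 99)),
)
_objects = st.one_of(_subjects, _literals)


@settings(max_examples=60, deadline=None)
@given(st.lists(st.tuples(_subjects, _predicates, _objects), max_size=25))
def test_roundtrip_property(triples):
    """parse(serialize(S)) equals S for arbitrary generated statement sets."""
    sset = oc.StatementSet.from_statements(
        [oc.Statement(s, p, o, EX) for s, p, o in triples], origin_ns=EX
    )
    assert sset.multiset_equal(oc.parse_owl(oc.serialize_owl(sset)))


class TestClassification:
    def test_metaclass_detected_via_class_instances(self):
        sset = oc.StatementSet.from_statements(
            [
                stmt(EX + "DataStructure", RDF_TYPE, OWL_CLASS),
                stmt(EX + "case", RDF_TYPE, EX + "DataStructure"),
                stmt(EX + "case", RDF_TYPE, OWL_CLASS),
            ],
            origin_ns=EX,
        )
        kinds = oc.classify_resources(sset)
        assert kinds[EX + "DataStructure"] is oc.ResourceKind.METACLASS
        assert kinds[EX + "case"] is oc.ResourceKind.NAMED_CLASS

    def test_contradictory_typing_rejected(self):
        sset = oc.StatementSet.from_statements(
            [
                stmt(EX + "x", RDF_TYPE, OWL_CLASS),
                stmt(EX + "x", RDF_TYPE, OWL_DATATYPE_PROPERTY),
            ],
            origin_ns=EX,
        )
        with pytest.raises(ContradictoryTypingError):
            oc.classify_resources(sset)

    def test_total_and_order_stable(self):
        statements = [
            stmt(EX + "C", RDF_TYPE, OWL_CLASS),
            stmt(EX + "D", RDFS_SUBCLASSOF, EX + "C"),
            stmt(EX + "p", RDF_TYPE, OWL_OBJECT_PROPERTY),
            stmt(EX + "i", RDF_TYPE, EX + "D"),
            stmt(EX + "i", EX + "p", EX + "j"),
        ]
        sset = oc.StatementSet.from_statements(statements, origin_ns=EX)
        kinds = oc.classify_resources(sset)
        mentioned = {s.subject for s in sset} | {
            s.object for s in sset if isinstance(s.object, str)
        } | {s.predicate for s in sset}
        assert set(kinds) >= mentioned  # total
        rev = oc.StatementSet.from_statements(
            list(reversed(statements)), origin_ns=EX
        )
        assert oc.classify_resources(rev) == kinds
        assert kinds[EX + "j"] is oc.ResourceKind.INDIVIDUAL

    def test_classification_matches_bruteforce_rules(self):
        """Spot-check against an independent rule-by-rule evaluation."""
        import random

        rng = random.Random(5)
        statements = []
        for i in range(8):
            statements.append(stmt(EX + f"C{i}", RDF_TYPE, OWL_CLASS))
        for i in range(1, 8):
            statements.append(
                stmt(EX + f"C{i}", RDFS_SUBCLASSOF, EX + f"C{rng.randrange(i)}")
            )
        for i in range(4):
            statements.append(stmt(EX + f"q{i}", RDF_TYPE, OWL_DATATYPE_PROPERTY))
        for i in range(10):
            statements.append(
                stmt(EX + f"i{i}", RDF_TYPE, EX + f"C{rng.randrange(8)}")
            )
        sset = oc.StatementSet.from_statements(statements, origin_ns=EX)
        kinds = oc.classify_resources(sset)
        # brute-force: evaluate each rule over the raw triple list
        triples = sset.triples()
        for r, kind in kinds.items():
            explicitly_class = (r, RDF_TYPE, OWL_CLASS) in triples
            is_prop = (r, RDF_TYPE, OWL_DATATYPE_PROPERTY) in triples
            typed_by_user = any(
                s == r and p == RDF_TYPE and isinstance(o, str) and o.startswith(EX)
                for s, p, o in triples
            )
            if explicitly_class:
                assert kind in (
                    oc.ResourceKind.NAMED_CLASS,
                    oc.ResourceKind.METACLASS,
                )
            elif is_prop:
                assert kind is oc.ResourceKind.DATATYPE_PROPERTY
            elif typed_by_user:
                assert kind is oc.ResourceKind.INDIVIDUAL


class TestImportClosure:
    def _onto(self, iri, imports=()):
        statements = [oc.Statement(iri, RDF_TYPE, OWL_ONTOLOGY, iri + "#")]
        statements += [
            oc.Statement(iri, OWL_IMPORTS, imp, iri + "#") for imp in imports
        ]
        return oc.StatementSet.from_statements(statements)

    def test_no_imports(self):
        root = self._onto(EX + "root")
        assert oc.import_closure(root, lambda iri: None) == [root]

    def test_chain_topological_order(self):
        c = self._onto("http://x/C")
        b = self._onto("http://x/B", ["http://x/C"])
        a = self._onto("http://x/A", ["http://x/B"])
        resolver = {"http://x/B": b, "http://x/C": c}.__getitem__
        order = [s.ontology_iri for s in oc.import_closure(a, resolver)]
        assert order == ["http://x/C", "http://x/B", "http://x/A"]

    def test_diamond_imports_once_in_valid_order(self):
        d = self._onto("http://x/D")
        b = self._onto("http://x/B", ["http://x/D"])
        c = self._onto("http://x/C", ["http://x/D"])
        a = self._onto("http://x/A", ["http://x/B", "http://x/C"])
        resolver = {
            "http://x/B": b, "http://x/C": c, "http://x/D": d
        }.__getitem__
        order = [s.ontology_iri for s in oc.import_closure(a, resolver)]
        assert len(order) == 4 and order.count("http://x/D") == 1
        assert order.index("http://x/D") < order.index("http://x/B")
        assert order.index("http://x/D") < order.index("http://x/C")
        assert order[-1] == "http://x/A"

    def test_cycle_reported(self):
        a = self._onto("http://x/A", ["http://x/B"])
        b = self._onto("http://x/B", ["http://x/A"])
        with pytest.raises(ImportCycleError):
            oc.import_closure(a, {"http://x/A": a, "http://x/B": b}.__getitem__)

    def test_unresolvable_import_named(self):
        a = self._onto("http://x/A", ["http://x/missing"])
        with pytest.raises(UnresolvableImportError, match="missing"):
            oc.import_closure(a, {}.__getitem__)
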