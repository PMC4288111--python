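"""Statement-level OWL model and serialization I/O.

This is the interchange layer of the engine: every other module consumes
ontologies as :class:`StatementSet` objects — flat collections of
subject–predicate–object assertions.  Parsing delegates to :mod:`rdflib`;
RDF/XML serialization is a deliberately small, flat writer whose output is
byte-deterministic for a given statement set (the persistence and fixture
layers rely on that contract).

Blank nodes are accepted on input but skolemized to stable local labels
(``_:b0``, ``_:b1``, ...) derived from a content signature, because the
storage layer is identity-based and round-trip comparisons are defined
modulo blank-node relabeling.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import rdflib
from lxml import etree

from .exceptions import (
    ContradictoryTypingError,
    ImportCycleError,
    ParseError,
    UnresolvableImportError,
    UnsupportedDatatypeError,
    UnsupportedDialectError,
)
from . import namespaces as ns
from .namespaces import (
    DATATYPE_IRI,
    DATATYPE_TAG,
    OWL_ANNOTATION_PROPERTY,
    OWL_CLASS,
    OWL_DATATYPE_PROPERTY,
    OWL_IMPORTS,
    OWL_OBJECT_PROPERTY,
    OWL_ONTOLOGY,
    RDF_TYPE,
    RDFS_CLASS,
    RDFS_DOMAIN,
    RDFS_RANGE,
    RDFS_SUBCLASSOF,
    RDFS_SUBPROPERTYOF,
    is_builtin,
    split_iri,
)

_DIALECT_FORMATS = {"rdfxml": "xml", "turtle": "turtle"}


@dataclass(frozen=True)
class IRI:
    """An absolute IRI split into namespace and local name.

    The namespace always ends in ``#`` or ``/`` so that concatenation of the
    two parts reproduces the full IRI.
    """

    namespace: str
    local_name: str

    @classmethod
    def parse(cls, iri: str) -> "IRI":
        namespace, local = split_iri(iri)
        return cls(namespace, local)

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.namespace + self.local_name


@dataclass(frozen=True, order=True)
class Literal:
    """A typed literal value: lexical form plus a datatype tag.

    Supported tags: string, integer, float, boolean, date, datetime.
    """

    lexical: str
    datatype: str = "string"

    def __post_init__(self):
        if self.datatype not in DATATYPE_IRI:
            raise UnsupportedDatatypeError(
                f"unsupported literal datatype tag {self.datatype!r}"
            )

    def to_python(self):
        """Coerce the lexical form to the matching Python value."""
        import datetime as _dt

        tag = self.datatype
        if tag == "string":
            return self.lexical
        if tag == "integer":
            return int(self.lexical)
        if tag == "float":
            return float(self.lexical)
        if tag == "boolean":
            return self.lexical.strip().lower() in ("true", "1")
        if tag == "date":
            return _dt.date.fromisoformat(self.lexical)
        if tag == "datetime":
            return _dt.datetime.fromisoformat(self.lexical)
        raise UnsupportedDatatypeError(tag)  # pragma: no cover

    def __repr__(self):
        return f'"{self.lexical}"^^{self.datatype}'


def is_blank(term: str) -> bool:
    return isinstance(term, str) and term.startswith("_:")


@dataclass(frozen=True)
class Statement:
    """One subject–predicate–object assertion.

    ``subject`` is an IRI string or a blank-node label (``_:label``);
    ``predicate`` is always an IRI string; ``object`` is an IRI string, a
    blank-node label, or a :class:`Literal`.  ``origin_ns`` records the
    namespace of the ontology the statement belongs to.
    """

    subject: str
    predicate: str
    object: object
    origin_ns: str = ""

    def triple(self):
        return (self.subject, self.predicate, self.object)

    def sort_key(self):
        return (self.subject, self.predicate, _object_key(self.object))

    def __repr__(self):
        return f"({self.subject} {self.predicate} {self.object!r})"


def _object_key(obj):
    if isinstance(obj, Literal):
        return ("L", obj.datatype, obj.lexical)
    return ("R", obj)


class ResourceKind(str, enum.Enum):
    NAMED_CLASS = "named_class"
    METACLASS = "metaclass"
    DATATYPE_PROPERTY = "datatype_property"
    OBJECT_PROPERTY = "object_property"
    ANNOTATION_PROPERTY = "annotation_property"
    INDIVIDUAL = "individual"
    ONTOLOGY = "ontology"
    DATATYPE = "datatype"


@dataclass
class StatementSet:
    """A normalized collection of statements belonging to one ontology.

    Normalization removes exact duplicates, sorts statements into canonical
    (subject, predicate, object) order, and relabels blank nodes with stable
    content-derived labels.  ``ontology_iri`` and ``imports`` mirror the
    ontology-header statements present in the set.
    """

    statements: list = field(default_factory=list)
    ontology_iri: str | None = None
    imports: list = field(default_factory=list)

    @classmethod
    def from_statements(cls, statements, origin_ns: str | None = None):
        stmts = list(statements)
        ontology_iri = None
        for s in stmts:
            if s.predicate == RDF_TYPE and s.object == OWL_ONTOLOGY:
                if ontology_iri is None or s.subject < ontology_iri:
                    ontology_iri = s.subject
        if origin_ns is None:
            origin_ns = ontology_ns(ontology_iri) if ontology_iri else ""
        stmts = [
            Statement(s.subject, s.predicate, s.object, origin_ns) for s in stmts
        ]
        stmts = _relabel_blanks(stmts)
        # dedupe on the triple, keep canonical order
        seen = set()
        out = []
        for s in sorted(stmts, key=Statement.sort_key):
            key = (s.subject, s.predicate, _object_key(s.object))
            if key not in seen:
                seen.add(key)
                out.append(s)
        imports = sorted(
            s.object
            for s in out
            if s.predicate == OWL_IMPORTS and s.subject == ontology_iri
        )
        return cls(out, ontology_iri, imports)

    @property
    def origin_ns(self) -> str:
        if self.statements:
            return self.statements[0].origin_ns
        return ontology_ns(self.ontology_iri) if self.ontology_iri else ""

    def triples(self):
        return [s.triple() for s in self.statements]

    def multiset_equal(self, other: "StatementSet") -> bool:
        """Statement-multiset equality modulo blank-node relabeling."""
        a = sorted(s.sort_key() for s in _relabel_blanks(self.statements))
        b = sorted(s.sort_key() for s in _relabel_blanks(other.statements))
        return a == b

    def __len__(self):
        return len(self.statements)

    def __iter__(self):
        return iter(self.statements)


def ontology_ns(ontology_iri: str) -> str:
    """Derive the namespace owned by an ontology from its IRI."""
    if ontology_iri.endswith(("#", "/")):
        return ontology_iri
    return ontology_iri + "#"


def _blank_signature(label, statements):
    """Content signature of a blank node: its non-blank neighborhood."""
    sig = []
    for s in statements:
        if s.subject == label:
            if isinstance(s.object, str) and is_blank(s.object):
                sig.append(("s", s.predicate, ("B", "")))
            else:
                sig.append(("s", s.predicate, _object_key(s.object)))
        if isinstance(s.object, str) and s.object == label:
            sig.append(("o", s.predicate, "B" if is_blank(s.subject) else s.subject))
    return tuple(sorted(sig))


def _relabel_blanks(statements):
    """Assign stable labels _:b0, _:b1 ... ordered by content signature."""
    labels = set()
    for s in statements:
        if is_blank(s.subject):
            labels.add(s.subject)
        if isinstance(s.object, str) and is_blank(s.object):
            labels.add(s.object)
    if not labels:
        return list(statements)
    ordered = sorted(labels, key=lambda l: (_blank_signature(l, statements), l))
    mapping = {old: f"_:b{i}" for i, old in enumerate(ordered)}

    def sub(term):
        if isinstance(term, str) and is_blank(term):
            return mapping[term]
        return term

    return [
        Statement(sub(s.subject), s.predicate, sub(s.object), s.origin_ns)
        for s in statements
    ]


# ---------------------------------------------------------------------------
# parsing


def _term_from_rdflib(term):
    if isinstance(term, rdflib.BNode):
        return "_:" + str(term)
    if isinstance(term, rdflib.Literal):
        if term.datatype is None:
            return Literal(str(term), "string")
        tag = DATATYPE_TAG.get(str(term.datatype))
        if tag is None:
            raise UnsupportedDatatypeError(
                f"unsupported literal datatype {term.datatype}"
            )
        return Literal(str(term), tag)
    return str(term)


def parse_owl(document: str, dialect: str = "rdfxml") -> StatementSet:
    """Parse an OWL serialization into a normalized :class:`StatementSet`.

    Raises :class:`ParseError` on malformed input (the rdflib message carries
    line/position information for RDF/XML) and
    :class:`UnsupportedDialectError` for dialects other than rdfxml/turtle.
    """
    fmt = _DIALECT_FORMATS.get(dialect)
    if fmt is None:
        raise UnsupportedDialectError(
            f"unsupported dialect {dialect!r}; supported: rdfxml, turtle"
        )
    graph = rdflib.Graph()
    try:
        graph.parse(data=document, format=fmt)
    except UnsupportedDatatypeError:
        raise
    except Exception as exc:
        raise ParseError(f"malformed {dialect} document: {exc}") from exc
    statements = [
        Statement(
            _term_from_rdflib(s), str(p), _term_from_rdflib(o)
        )
        for s, p, o in graph
        if not isinstance(p, rdflib.BNode)
    ]
    return StatementSet.from_statements(statements)


# ---------------------------------------------------------------------------
# serialization


def _qname_split(iri: str):
    namespace, local = split_iri(iri)
    if not local or not (local[0].isalpha() or local[0] == "_"):
        raise ParseError(f"cannot derive an XML qualified name for {iri}")
    return namespace, local


def serialize_owl(stmts: StatementSet, dialect: str = "rdfxml") -> str:
    """Serialize a statement set; output is deterministic per dialect.

    For the canonical rdfxml dialect two serializations of the same set are
    byte-identical: statements are written in canonical sort order as flat
    ``rdf:Description`` groups with sorted namespace prefixes.
    """
    fmt = _DIALECT_FORMATS.get(dialect)
    if fmt is None:
        raise UnsupportedDialectError(
            f"unsupported dialect {dialect!r}; supported: rdfxml, turtle"
        )
    ordered = sorted(_relabel_blanks(stmts.statements), key=Statement.sort_key)
    if dialect == "turtle":
        graph = rdflib.Graph()
        for s in ordered:
            graph.add(_triple_to_rdflib(s))
        return graph.serialize(format="turtle")

    # collect predicate namespaces for prefix declarations
    pred_ns = sorted({_qname_split(s.predicate)[0] for s in ordered})
    nsmap = {"rdf": ns.RDF_NS}
    prefix_of = {ns.RDF_NS: "rdf"}
    counter = 1
    for n in pred_ns:
        if n not in prefix_of:
            prefix_of[n] = f"ns{counter}"
            nsmap[f"ns{counter}"] = n
            counter += 1
    RDF = "{%s}" % ns.RDF_NS
    root = etree.Element(RDF + "RDF", nsmap=nsmap)
    current_subject = object()
    desc = None
    for s in ordered:
        if s.subject != current_subject:
            desc = etree.SubElement(root, RDF + "Description")
            if is_blank(s.subject):
                desc.set(RDF + "nodeID", s.subject[2:])
            else:
                desc.set(RDF + "about", s.subject)
            current_subject = s.subject
        pns, plocal = _qname_split(s.predicate)
        el = etree.SubElement(desc, "{%s}%s" % (pns, plocal))
        obj = s.object
        if isinstance(obj, Literal):
            el.text = obj.lexical
            if obj.datatype != "string":
                el.set(RDF + "datatype", DATATYPE_IRI[obj.datatype])
        elif is_blank(obj):
            el.set(RDF + "nodeID", obj[2:])
        else:
            el.set(RDF + "resource", obj)
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="utf-8"
    ).decode("utf-8")


def _triple_to_rdflib(s: Statement):
    def term(t, position):
        if isinstance(t, Literal):
            dt = None if t.datatype == "string" else rdflib.URIRef(
                DATATYPE_IRI[t.datatype]
            )
            return rdflib.Literal(t.lexical, datatype=dt)
        if is_blank(t):
            return rdflib.BNode(t[2:])
        return rdflib.URIRef(t)

    return (term(s.subject, 0), rdflib.URIRef(s.predicate), term(s.object, 2))


# ---------------------------------------------------------------------------
# resource classification

_BUILTIN_KINDS = {
    OWL_CLASS: ResourceKind.METACLASS,
    RDFS_CLASS: ResourceKind.METACLASS,
    ns.OWL_NS + "Restriction": ResourceKind.METACLASS,
    ns.OWL_THING: ResourceKind.NAMED_CLASS,
    OWL_ONTOLOGY: ResourceKind.NAMED_CLASS,
    OWL_OBJECT_PROPERTY: ResourceKind.NAMED_CLASS,
    OWL_DATATYPE_PROPERTY: ResourceKind.NAMED_CLASS,
    OWL_ANNOTATION_PROPERTY: ResourceKind.NAMED_CLASS,
    ns.OWL_FUNCTIONAL_PROPERTY: ResourceKind.NAMED_CLASS,
    RDF_TYPE: ResourceKind.OBJECT_PROPERTY,
    RDFS_SUBCLASSOF: ResourceKind.OBJECT_PROPERTY,
    RDFS_SUBPROPERTYOF: ResourceKind.OBJECT_PROPERTY,
    RDFS_DOMAIN: ResourceKind.OBJECT_PROPERTY,
    RDFS_RANGE: ResourceKind.OBJECT_PROPERTY,
    OWL_IMPORTS: ResourceKind.OBJECT_PROPERTY,
    ns.RDFS_LABEL: ResourceKind.ANNOTATION_PROPERTY,
    ns.RDFS_COMMENT: ResourceKind.ANNOTATION_PROPERTY,
    ns.OWL_VERSION_INFO: ResourceKind.ANNOTATION_PROPERTY,
}

_CLASS_TYPES = {OWL_CLASS, RDFS_CLASS}
_PROPERTY_TYPES = {
    OWL_OBJECT_PROPERTY: ResourceKind.OBJECT_PROPERTY,
    OWL_DATATYPE_PROPERTY: ResourceKind.DATATYPE_PROPERTY,
    OWL_ANNOTATION_PROPERTY: ResourceKind.ANNOTATION_PROPERTY,
}


def classify_resources(stmts: StatementSet) -> dict:
    """Map every mentioned resource to exactly one :class:`ResourceKind`.

    Classification is rule-based over the asserted statements and is stable
    under statement reordering.  A resource typed both as a class and as a
    property raises :class:`ContradictoryTypingError` listing the offending
    statements.
    """
    mentioned = set()
    class_evidence = set()
    subclass_pairs = []
    declared_prop = {}
    prop_use = set()
    literal_object_preds = set()
    typed = {}
    ontologies = set()
    instance_of = {}

    for s in stmts:
        mentioned.add(s.subject)
        mentioned.add(s.predicate)
        if not isinstance(s.object, Literal):
            mentioned.add(s.object)
        else:
            literal_object_preds.add(s.predicate)
        prop_use.add(s.predicate)
        if s.predicate == RDF_TYPE:
            typed.setdefault(s.subject, set()).add(s.object)
            if s.object == OWL_ONTOLOGY:
                ontologies.add(s.subject)
            elif s.object in _CLASS_TYPES:
                class_evidence.add(s.subject)
            elif s.object in _PROPERTY_TYPES:
                declared_prop.setdefault(s.subject, set()).add(
                    _PROPERTY_TYPES[s.object]
                )
            if not is_builtin(str(s.object)) and not isinstance(s.object, Literal):
                class_evidence.add(s.object)
                instance_of.setdefault(s.object, set()).add(s.subject)
        elif s.predicate == RDFS_SUBCLASSOF:
            class_evidence.add(s.subject)
            if not isinstance(s.object, Literal):
                class_evidence.add(s.object)
            subclass_pairs.append((s.subject, s.object))
        elif s.predicate == RDFS_SUBPROPERTYOF:
            prop_use.add(s.subject)
            if not isinstance(s.object, Literal):
                prop_use.add(s.object)
        elif s.predicate in (RDFS_DOMAIN, RDFS_RANGE):
            prop_use.add(s.subject)
            if (
                s.predicate == RDFS_DOMAIN
                and not isinstance(s.object, Literal)
                and not is_builtin(s.object)
            ):
                class_evidence.add(s.object)
            if (
                s.predicate == RDFS_RANGE
                and not isinstance(s.object, Literal)
                and not is_builtin(s.object)
            ):
                class_evidence.add(s.object)

    subclass_of_class = {
        c for c, p in subclass_pairs if p in _CLASS_TYPES
    }

    result = {}
    for r in sorted(mentioned):
        if is_builtin(r) and r in _BUILTIN_KINDS:
            result[r] = _BUILTIN_KINDS[r]
            continue
        if r.startswith(ns.XSD_NS):
            result[r] = ResourceKind.DATATYPE
            continue
        if r in ontologies:
            result[r] = ResourceKind.ONTOLOGY
            continue
        kinds = declared_prop.get(r, set())
        if kinds and r in class_evidence:
            offending = [
                s
                for s in stmts
                if s.subject == r
                and s.predicate in (RDF_TYPE, RDFS_SUBCLASSOF)
            ]
            raise ContradictoryTypingError(r, offending)
        if kinds:
            if (
                ResourceKind.DATATYPE_PROPERTY in kinds
                and ResourceKind.OBJECT_PROPERTY in kinds
            ):
                offending = [
                    s for s in stmts if s.subject == r and s.predicate == RDF_TYPE
                ]
                raise ContradictoryTypingError(r, offending)
            for k in (
                ResourceKind.DATATYPE_PROPERTY,
                ResourceKind.OBJECT_PROPERTY,
                ResourceKind.ANNOTATION_PROPERTY,
            ):
                if k in kinds:
                    result[r] = k
                    break
            continue
        if r in class_evidence:
            has_class_instance = any(
                i in class_evidence for i in instance_of.get(r, ())
            )
            if has_class_instance or r in subclass_of_class:
                result[r] = ResourceKind.METACLASS
            else:
                result[r] = ResourceKind.NAMED_CLASS
            continue
        if r in prop_use:
            # undeclared but used as a property: infer kind from object shape
            if r in literal_object_preds:
                result[r] = ResourceKind.DATATYPE_PROPERTY
            else:
                result[r] = ResourceKind.OBJECT_PROPERTY
            continue
        result[r] = ResourceKind.INDIVIDUAL
    return result


# ---------------------------------------------------------------------------
# import closure


def import_closure(root: StatementSet, resolver) -> list:
    """Resolve the transitive owl:imports closure of ``root``.

    ``resolver`` is a callable mapping an ontology IRI to its
    :class:`StatementSet`.  Returns the closure in topological order
    (imported ontologies before their importers, the root last); each
    ontology appears exactly once.  Raises :class:`ImportCycleError` on a
    cyclic import graph and :class:`UnresolvableImportError` when the
    resolver cannot supply an import.
    """
    order = []
    done = set()
    path = []

    def visit(sset: StatementSet, iri):
        if iri in path:
            raise ImportCycleError(path[path.index(iri):] + [iri])
        if iri in done:
            return
        path.append(iri)
        for imp in sorted(sset.imports):
            if imp in done:
                continue
            try:
                imported = resolver(imp)
            except ImportCycleError:
                raise
            except Exception as exc:
                raise UnresolvableImportError(
                    f"cannot resolve imported ontology {imp}: {exc}"
                ) from exc
            if imported is None:
                raise UnresolvableImportError(
                    f"cannot resolve imported ontology {imp}"
                )
            visit(imported, imp)
        path.pop()
        done.add(iri)
        order.append(sset)

    visit(root, root.ontology_iri or "<root>")
    return order
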