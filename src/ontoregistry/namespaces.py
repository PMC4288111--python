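"""Well-known vocabulary IRIs and the supported literal datatype set."""

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
OWL_NS = "http://www.w3.org/2002/07/owl#"
XSD_NS = "http://www.w3.org/2001/XMLSchema#"

RDF_TYPE = RDF_NS + "type"
RDFS_SUBCLASSOF = RDFS_NS + "subClassOf"
RDFS_SUBPROPERTYOF = RDFS_NS + "subPropertyOf"
RDFS_DOMAIN = RDFS_NS + "domain"
RDFS_RANGE = RDFS_NS + "range"
RDFS_LABEL = RDFS_NS + "label"
RDFS_COMMENT = RDFS_NS + "comment"
RDFS_CLASS = RDFS_NS + "Class"

OWL_CLASS = OWL_NS + "Class"
OWL_THING = OWL_NS + "Thing"
OWL_ONTOLOGY = OWL_NS + "Ontology"
OWL_IMPORTS = OWL_NS + "imports"
OWL_OBJECT_PROPERTY = OWL_NS + "ObjectProperty"
OWL_DATATYPE_PROPERTY = OWL_NS + "DatatypeProperty"
OWL_ANNOTATION_PROPERTY = OWL_NS + "AnnotationProperty"
OWL_FUNCTIONAL_PROPERTY = OWL_NS + "FunctionalProperty"
OWL_VERSION_INFO = OWL_NS + "versionInfo"

#: Closed set of supported literal datatypes: tag -> canonical XSD IRI.
DATATYPE_IRI = {
    "string": XSD_NS + "string",
    "integer": XSD_NS + "integer",
    "float": XSD_NS + "double",
    "boolean": XSD_NS + "boolean",
    "date": XSD_NS + "date",
    "datetime": XSD_NS + "dateTime",
}

#: XSD IRI -> tag, including aliases accepted on input.
DATATYPE_TAG = {
    XSD_NS + "string": "string",
    XSD_NS + "integer": "integer",
    XSD_NS + "int": "integer",
    XSD_NS + "long": "integer",
    XSD_NS + "nonNegativeInteger": "integer",
    XSD_NS + "positiveInteger": "integer",
    XSD_NS + "float": "float",
    XSD_NS + "double": "float",
    XSD_NS + "decimal": "float",
    XSD_NS + "boolean": "boolean",
    XSD_NS + "date": "date",
    XSD_NS + "dateTime": "datetime",
}

BUILTIN_NAMESPACES = (RDF_NS, RDFS_NS, OWL_NS, XSD_NS)


def is_builtin(iri: str) -> bool:
    """True for terms of the RDF/RDFS/OWL/XSD vocabularies."""
    return iri.startswith(BUILTIN_NAMESPACES)


def split_iri(iri: str) -> tuple[str, str]:
    """Split an absolute IRI into (namespace, local name).

    The namespace ends at the last ``#`` or, failing that, the last ``/``.
    """
    for sep in ("#", "/"):
        pos = iri.rfind(sep)
        if pos > 0:
            return iri[: pos + 1], iri[pos + 1 :]
    return iri, ""


def local_name(iri: str) -> str:
    return split_iri(iri)[1]
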