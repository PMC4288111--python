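"""The built-in form metamodel and application-ontology validation.

An application (a registry) is itself an OWL ontology written against a
fixed metamodel vocabulary: the application is an instance of the
``Application`` metaclass, each data-entry form is a class that is an
instance of the ``DataStructure`` metaclass (and a subclass of
``ApplicationItem``), form fields are properties typed by one of the
``FormElement`` widget subclasses, and per-field behavior is controlled by
``web*`` facet properties (grid position, description/mandatory/id flags,
edit locking, and dependent-cascade marking).  Constrained fields point to a
subclass of ``AllowedValues`` (or ``CodedValues`` for coded options) whose
individuals are the permitted options, ordered by an integer rank.

This module ships that vocabulary as a statement set, validates application
ontologies against it (a fixed list of coded rules), and compiles per-form
field specifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from collections import defaultdict
from functools import lru_cache
import json

from .exceptions import UnknownResourceError
from .namespaces import (
    DATATYPE_TAG,
    OWL_CLASS,
    OWL_DATATYPE_PROPERTY,
    OWL_OBJECT_PROPERTY,
    OWL_ONTOLOGY,
    OWL_VERSION_INFO,
    RDF_TYPE,
    RDFS_DOMAIN,
    RDFS_RANGE,
    RDFS_SUBCLASSOF,
    XSD_NS,
    is_builtin,
    local_name,
)
from .owl_core import Literal, Statement, StatementSet

#: Namespace of the built-in metamodel vocabulary.
MM_ONTOLOGY_IRI = "https://ontoregistry.org/ns/metamodel"
MM = MM_ONTOLOGY_IRI + "#"
METAMODEL_VERSION = "1.0"

APPLICATION = MM + "Application"
DATA_STRUCTURE = MM + "DataStructure"
APPLICATION_ITEM = MM + "ApplicationItem"
MENU_ITEM = MM + "MenuItem"
FORM_ELEMENT = MM + "FormElement"
REPORTABLE = MM + "Reportable"
ALLOWED_VALUES = MM + "AllowedValues"
CODED_VALUES = MM + "CodedValues"
ORDERED_ITEM = MM + "OrderedItem"
DATA_EXTRACTION = MM + "DataExtraction"

#: The widget vocabulary: subclasses of FormElement.
WIDGETS = (
    "Checkbox",
    "Combobox",
    "Graphic",
    "HyperlinkProperty",
    "ImageProperty",
    "LiteralProperty",
    "MultilineStringProperty",
    "Password",
    "RadioButton",
    "SingleCell",
    "SubForm",
)
WIDGET_IRIS = {w: MM + w for w in WIDGETS}
WIDGET_SET = frozenset(WIDGET_IRIS.values())

WEB_COLUMN = MM + "webColumn"
WEB_ROW = MM + "webRow"
WEB_DESCRIPTION = MM + "webDescriptionProperty"
WEB_MANDATORY = MM + "webMandatoryProperty"
WEB_ID = MM + "webIdProperty"
WEB_EDITION_DISABLED = MM + "webEditionDisabled"
WEB_DIRECTLY_DEPENDENT = MM + "webDirectlyDependent"

FACET_PROPERTIES = (
    WEB_COLUMN,
    WEB_ROW,
    WEB_DESCRIPTION,
    WEB_MANDATORY,
    WEB_ID,
    WEB_EDITION_DISABLED,
    WEB_DIRECTLY_DEPENDENT,
)

ITEM_ORDER = MM + "itemOrder"
CODE = MM + "code"
EXTRACTION_TARGET = MM + "extractionTarget"
EXTRACTION_RECURSIVE = MM + "extractionRecursive"

#: Access-control vocabulary: parsed if present, never enforced.
ACCESS_CLASSES = (
    MM + "Role",
    MM + "UnderAuthorization",
    MM + "Organization",
    MM + "Authorization",
)

_XSD_INT = XSD_NS + "integer"
_XSD_BOOL = XSD_NS + "boolean"
_XSD_STR = XSD_NS + "string"


@lru_cache(maxsize=1)
def metamodel_statements() -> StatementSet:
    """The fixed metamodel vocabulary as a normalized statement set."""
    s = []

    def add(subject, predicate, obj):
        s.append(Statement(subject, predicate, obj, MM))

    add(MM_ONTOLOGY_IRI, RDF_TYPE, OWL_ONTOLOGY)
    add(MM_ONTOLOGY_IRI, OWL_VERSION_INFO, Literal(METAMODEL_VERSION))

    # metaclasses: their instances are classes
    for metaclass in (APPLICATION, DATA_STRUCTURE, REPORTABLE):
        add(metaclass, RDF_TYPE, OWL_CLASS)
        add(metaclass, RDFS_SUBCLASSOF, OWL_CLASS)

    plain_classes = (
        APPLICATION_ITEM,
        MENU_ITEM,
        FORM_ELEMENT,
        ORDERED_ITEM,
        ALLOWED_VALUES,
        CODED_VALUES,
        DATA_EXTRACTION,
    ) + ACCESS_CLASSES
    for cls in plain_classes:
        add(cls, RDF_TYPE, OWL_CLASS)
    add(ALLOWED_VALUES, RDFS_SUBCLASSOF, ORDERED_ITEM)
    add(CODED_VALUES, RDFS_SUBCLASSOF, ALLOWED_VALUES)

    for widget_iri in WIDGET_IRIS.values():
        add(widget_iri, RDF_TYPE, OWL_CLASS)
        add(widget_iri, RDFS_SUBCLASSOF, FORM_ELEMENT)

    for facet in FACET_PROPERTIES:
        add(facet, RDF_TYPE, OWL_DATATYPE_PROPERTY)
        add(facet, RDFS_RANGE, _XSD_INT if facet in (WEB_COLUMN, WEB_ROW) else _XSD_BOOL)

    add(ITEM_ORDER, RDF_TYPE, OWL_DATATYPE_PROPERTY)
    add(ITEM_ORDER, RDFS_DOMAIN, ORDERED_ITEM)
    add(ITEM_ORDER, RDFS_RANGE, _XSD_INT)
    add(CODE, RDF_TYPE, OWL_DATATYPE_PROPERTY)
    add(CODE, RDFS_DOMAIN, CODED_VALUES)
    add(CODE, RDFS_RANGE, _XSD_STR)
    add(EXTRACTION_TARGET, RDF_TYPE, OWL_OBJECT_PROPERTY)
    add(EXTRACTION_TARGET, RDFS_DOMAIN, DATA_EXTRACTION)
    add(EXTRACTION_RECURSIVE, RDF_TYPE, OWL_DATATYPE_PROPERTY)
    add(EXTRACTION_RECURSIVE, RDFS_DOMAIN, DATA_EXTRACTION)
    add(EXTRACTION_RECURSIVE, RDFS_RANGE, _XSD_BOOL)

    return StatementSet.from_statements(s, origin_ns=MM)


# ---------------------------------------------------------------------------
# graph view


class GraphView:
    """Index over a merged (application + metamodel) statement set."""

    def __init__(self, *statement_sets):
        self._sp = defaultdict(list)
        self._types = defaultdict(set)
        self._instances = defaultdict(set)
        self._superclasses = defaultdict(set)
        self.statements = []
        for sset in statement_sets:
            for st in sset:
                self.statements.append(st)
                self._sp[(st.subject, st.predicate)].append(st.object)
                if st.predicate == RDF_TYPE and not isinstance(st.object, Literal):
                    self._types[st.subject].add(st.object)
                    self._instances[st.object].add(st.subject)
                elif st.predicate == RDFS_SUBCLASSOF and not isinstance(
                    st.object, Literal
                ):
                    self._superclasses[st.subject].add(st.object)

    def objects(self, subject, predicate):
        return self._sp.get((subject, predicate), [])

    def object(self, subject, predicate):
        vals = self.objects(subject, predicate)
        return vals[0] if vals else None

    def types(self, subject):
        return self._types.get(subject, set())

    def instances(self, cls):
        return self._instances.get(cls, set())

    def superclass_closure(self, cls):
        """All (transitive) superclasses of ``cls``, excluding itself."""
        out = set()
        frontier = [cls]
        while frontier:
            c = frontier.pop()
            for sup in self._superclasses.get(c, ()):
                if sup not in out:
                    out.add(sup)
                    frontier.append(sup)
        return out

    def is_subclass_of(self, cls, ancestor):
        return ancestor == cls or ancestor in self.superclass_closure(cls)

    # -- application-level views ------------------------------------------

    def applications(self):
        return sorted(self.instances(APPLICATION))

    def data_structures(self):
        return sorted(self.instances(DATA_STRUCTURE))

    def menu_properties(self):
        return sorted(self.instances(MENU_ITEM))

    def fields_of(self, ds):
        """Form-field properties: domain is ``ds`` and not a menu entry."""
        menu = set(self.menu_properties())
        out = []
        for subject, predicate in self._sp:
            if predicate == RDFS_DOMAIN and subject not in menu:
                if ds in self.objects(subject, RDFS_DOMAIN):
                    out.append(subject)
        return sorted(set(out))

    def facet_int(self, prop, facet):
        v = self.object(prop, facet)
        if isinstance(v, Literal):
            try:
                return int(v.lexical)
            except ValueError:
                return None
        return None

    def facet_bool(self, prop, facet):
        v = self.object(prop, facet)
        if isinstance(v, Literal):
            return v.lexical.strip().lower() in ("true", "1")
        return False

    def allowed_values_lists(self):
        """App-declared option list classes: proper subclasses of AllowedValues."""
        out = []
        for cls in self._superclasses:
            if cls.startswith(MM):
                continue
            if ALLOWED_VALUES in self.superclass_closure(cls):
                out.append(cls)
        return sorted(out)

    def is_reportable(self, ds):
        return REPORTABLE in self.superclass_closure(ds)


# ---------------------------------------------------------------------------
# field specifications


@dataclass(frozen=True)
class FieldFacets:
    """Per-field behavior flags; an id field is implicitly mandatory."""

    web_row: int | None = None
    web_column: int | None = None
    is_description: bool = False
    is_mandatory: bool = False
    is_id: bool = False
    edition_disabled: bool = False
    directly_dependent: bool = False

    def __post_init__(self):
        if self.is_id and not self.is_mandatory:
            object.__setattr__(self, "is_mandatory", True)


@dataclass(frozen=True)
class Option:
    iri: str
    label: str
    rank: int
    code: str | None = None


@dataclass(frozen=True)
class FieldSpec:
    """Compiled description of one form field."""

    property_iri: str
    widget: str  # widget local name, e.g. "SingleCell"
    facets: FieldFacets
    value_type: str  # datatype tag, "resource", or "options"
    target: str | None = None  # range class for resource/options values
    options: tuple = ()

    @property
    def label(self):
        return local_name(self.property_iri)


def _field_facets(g: GraphView, prop) -> FieldFacets:
    return FieldFacets(
        web_row=g.facet_int(prop, WEB_ROW),
        web_column=g.facet_int(prop, WEB_COLUMN),
        is_description=g.facet_bool(prop, WEB_DESCRIPTION),
        is_mandatory=g.facet_bool(prop, WEB_MANDATORY),
        is_id=g.facet_bool(prop, WEB_ID),
        edition_disabled=g.facet_bool(prop, WEB_EDITION_DISABLED),
        directly_dependent=g.facet_bool(prop, WEB_DIRECTLY_DEPENDENT),
    )


def _options_of(g: GraphView, list_cls):
    opts = []
    for inst in g.instances(list_cls):
        rank = g.facet_int(inst, ITEM_ORDER)
        code = g.object(inst, CODE)
        opts.append(
            Option(
                iri=inst,
                label=local_name(inst),
                rank=rank if rank is not None else 0,
                code=code.lexical if isinstance(code, Literal) else None,
            )
        )
    # rank order; ties broken by IRI lexical order
    return tuple(sorted(opts, key=lambda o: (o.rank, o.iri)))


def _widget_of(g: GraphView, prop):
    widgets = sorted(t for t in g.types(prop) if t in WIDGET_SET)
    return local_name(widgets[0]) if widgets else None


def field_specs(app: StatementSet, data_structure: str, graph: GraphView | None = None):
    """Compiled field specs of one form, ordered by (webRow, webColumn)."""
    g = graph or GraphView(app, metamodel_statements())
    if data_structure not in g.instances(DATA_STRUCTURE):
        raise UnknownResourceError(
            f"{data_structure} is not a DataStructure of this application"
        )
    specs = []
    for prop in g.fields_of(data_structure):
        facets = _field_facets(g, prop)
        rng = g.object(prop, RDFS_RANGE)
        widget = _widget_of(g, prop)
        value_type = "string"
        target = None
        options = ()
        if isinstance(rng, str):
            if rng in DATATYPE_TAG:
                value_type = DATATYPE_TAG[rng]
            elif ALLOWED_VALUES in g.superclass_closure(rng) or rng == ALLOWED_VALUES:
                value_type = "options"
                target = rng
                options = _options_of(g, rng)
            elif not is_builtin(rng):
                value_type = "resource"
                target = rng
        specs.append(
            FieldSpec(
                property_iri=prop,
                widget=widget or "SingleCell",
                facets=facets,
                value_type=value_type,
                target=target,
                options=options,
            )
        )
    return sorted(
        specs,
        key=lambda f: (
            f.facets.web_row if f.facets.web_row is not None else 10**9,
            f.facets.web_column if f.facets.web_column is not None else 10**9,
            f.property_iri,
        ),
    )


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Finding:
    code: str
    subject: str
    message: str


@dataclass
class ValidationReport:
    errors: list = dfield(default_factory=list)
    warnings: list = dfield(default_factory=list)

    @property
    def is_valid(self):
        return not self.errors

    def codes(self):
        return {f.code for f in self.errors} | {f.code for f in self.warnings}

    def to_dict(self):
        return {
            "is_valid": self.is_valid,
            "errors": [vars(f) for f in self.errors],
            "warnings": [vars(f) for f in self.warnings],
        }

    def to_json(self, **kw):
        kw.setdefault("indent", 2)
        kw.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kw)


# Stable rule codes.  LAYOUT_MISSING supplements the core rule set: a field
# without a grid position cannot be rendered.
APP_MISSING = "APP_MISSING"
FORM_NOT_APPLICATION_ITEM = "FORM_NOT_APPLICATION_ITEM"
FIELD_WIDGET_COUNT = "FIELD_WIDGET_COUNT"
MENU_MALFORMED = "MENU_MALFORMED"
GRID_COLLISION = "GRID_COLLISION"
OPTIONS_MISSING = "OPTIONS_MISSING"
CODE_MISSING = "CODE_MISSING"
ORDER_MISSING = "ORDER_MISSING"
SUBFORM_UNSUPPORTED = "SUBFORM_UNSUPPORTED"
DEPENDENT_NOT_OBJECT = "DEPENDENT_NOT_OBJECT"
ID_FIELD_DUPLICATE = "ID_FIELD_DUPLICATE"
LAYOUT_MISSING = "LAYOUT_MISSING"

#: Rule codes in their canonical order.
RULE_CODES = (
    APP_MISSING,
    FORM_NOT_APPLICATION_ITEM,
    FIELD_WIDGET_COUNT,
    MENU_MALFORMED,
    GRID_COLLISION,
    OPTIONS_MISSING,
    CODE_MISSING,
    ORDER_MISSING,
    SUBFORM_UNSUPPORTED,
    DEPENDENT_NOT_OBJECT,
    ID_FIELD_DUPLICATE,
)

_OPTION_WIDGETS = {WIDGET_IRIS["Combobox"], WIDGET_IRIS["RadioButton"]}


def validate_application(app: StatementSet) -> ValidationReport:
    """Check an application ontology against the metamodel rules.

    All findings are collected into the report; nothing raises.  The checks:

    1.  at least one Application instance exists;
    2.  every DataStructure instance is a subclass of ApplicationItem;
    3.  every field is an instance of exactly one FormElement widget;
    4.  menu entries are object properties linking DataStructures;
    5.  no two fields of one form share a (row, column) cell;
    6.  Combobox/RadioButton fields reference an AllowedValues subclass
        with at least one option instance;
    7.  options of CodedValues lists each carry a code;
    8.  options of AllowedValues lists each carry an integer rank;
    9.  SubForm fields are flagged unsupported (warning only);
    10. the dependent-cascade facet appears only on object properties;
    11. at most one id field per DataStructure.
    """
    g = GraphView(app, metamodel_statements())
    report = ValidationReport()

    def err(code, subject, message):
        report.errors.append(Finding(code, subject, message))

    def warn(code, subject, message):
        report.warnings.append(Finding(code, subject, message))

    # r1 -------------------------------------------------------------------
    if not g.applications():
        err(APP_MISSING, "", "no instance of the Application metaclass found")

    structures = g.data_structures()
    menu_props = g.menu_properties()
    ds_set = set(structures)

    # r2 -------------------------------------------------------------------
    for ds in structures:
        if APPLICATION_ITEM not in g.superclass_closure(ds):
            err(
                FORM_NOT_APPLICATION_ITEM,
                ds,
                "DataStructure is not a subclass of ApplicationItem",
            )

    # r3 / r5 / r9 / r11 / layout -----------------------------------------
    for ds in structures:
        grid = defaultdict(list)
        id_fields = []
        for prop in g.fields_of(ds):
            widgets = sorted(t for t in g.types(prop) if t in WIDGET_SET)
            if len(widgets) != 1:
                err(
                    FIELD_WIDGET_COUNT,
                    prop,
                    f"field has {len(widgets)} FormElement widget types, expected 1",
                )
            if WIDGET_IRIS["SubForm"] in widgets:
                warn(
                    SUBFORM_UNSUPPORTED,
                    prop,
                    "SubForm fields are not supported and will be skipped",
                )
            row = g.facet_int(prop, WEB_ROW)
            col = g.facet_int(prop, WEB_COLUMN)
            if row is None or col is None:
                err(LAYOUT_MISSING, prop, "field is missing webRow/webColumn")
            else:
                grid[(row, col)].append(prop)
            if g.facet_bool(prop, WEB_ID):
                id_fields.append(prop)
        for (row, col), props in sorted(grid.items()):
            if len(props) > 1:
                err(
                    GRID_COLLISION,
                    ds,
                    f"fields {sorted(props)} collide at (row {row}, col {col})",
                )
        if len(id_fields) > 1:
            err(
                ID_FIELD_DUPLICATE,
                ds,
                f"multiple id fields declared: {sorted(id_fields)}",
            )

    # r4 -------------------------------------------------------------------
    for prop in menu_props:
        problems = []
        if OWL_OBJECT_PROPERTY not in g.types(prop):
            problems.append("not an ObjectProperty")
        domain = g.object(prop, RDFS_DOMAIN)
        rng = g.object(prop, RDFS_RANGE)
        if domain not in ds_set:
            problems.append("domain is not a DataStructure")
        if rng not in ds_set:
            problems.append("range is not a DataStructure")
        if problems:
            err(MENU_MALFORMED, prop, "menu entry " + "; ".join(problems))

    # r6 -------------------------------------------------------------------
    for ds in structures:
        for prop in g.fields_of(ds):
            widgets = set(g.types(prop)) & _OPTION_WIDGETS
            if not widgets:
                continue
            rng = g.object(prop, RDFS_RANGE)
            ok = (
                isinstance(rng, str)
                and ALLOWED_VALUES in g.superclass_closure(rng)
                and len(g.instances(rng)) > 0
            )
            if not ok:
                err(
                    OPTIONS_MISSING,
                    prop,
                    "constrained field does not reference an AllowedValues "
                    "subclass with option instances",
                )

    # r7 / r8 --------------------------------------------------------------
    for list_cls in g.allowed_values_lists():
        coded = CODED_VALUES in g.superclass_closure(list_cls)
        for inst in sorted(g.instances(list_cls)):
            if coded and not isinstance(g.object(inst, CODE), Literal):
                err(CODE_MISSING, inst, "coded option carries no code")
            if g.facet_int(inst, ITEM_ORDER) is None:
                err(ORDER_MISSING, inst, "option carries no integer rank")

    # r10 ------------------------------------------------------------------
    for st in g.statements:
        if st.predicate == WEB_DIRECTLY_DEPENDENT and isinstance(st.object, Literal):
            if st.object.lexical.strip().lower() in ("true", "1"):
                if OWL_OBJECT_PROPERTY not in g.types(st.subject):
                    err(
                        DEPENDENT_NOT_OBJECT,
                        st.subject,
                        "dependent-cascade facet on a non-object property",
                    )

    return report
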