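"""Deterministic generators of synthetic registries and hierarchies.

Every module of the engine is testable without external data: this module
generates application ontologies shaped like deployed clinical registries
(a case root, menu-linked satellite forms, mixed widget kinds, coded
option lists, reportable and dependent structures), class hierarchies for
stress-testing the nested-set index, and instance populations entered
through the constraint-checking CRUD path.

Default parameters reflect the envelope of real deployments of this kind
of system: registries of a few hundred to 2000 cases with roughly 60 to
600 variables per case, and taxonomies up to the ~16,000-class range.
All generation is seed-deterministic: equal seeds give byte-identical
serialized fixtures.
"""

from __future__ import annotations

import datetime
import random
from dataclasses import dataclass

from . import hierarchy as hmod
from . import metamodel as mm
from .exceptions import OntoRegistryError
from .forms import Registry
from .namespaces import (
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
    local_name,
)
from .owl_core import Literal, Statement, StatementSet


@dataclass
class RegistryParams:
    """Shape of a generated registry; defaults sit inside the envelope of
    real deployments (cases in [200, 2000], 60–600 variables per case)."""

    n_data_structures: int = 8
    fields_per_structure: tuple = (6, 12)
    n_cases: int = 300
    children_per_structure: tuple = (1, 2)
    option_list_fraction: float = 0.3
    reportable_fraction: float = 0.25
    dependent_fraction: float = 0.4
    seed: int = 0
    name: str | None = None

    def __post_init__(self):
        if self.n_data_structures < 1:
            raise OntoRegistryError("need at least the case data structure")
        lo, hi = self.fields_per_structure
        if lo < 1 or hi < lo:
            raise OntoRegistryError("fields_per_structure range is infeasible")
        if self.n_cases < 0:
            raise OntoRegistryError("n_cases must be non-negative")
        if self.name is None:
            self.name = f"reg{self.seed:04d}"

    @property
    def namespace(self):
        return f"https://example.org/registry/{self.name}#"


@dataclass
class HierarchyParams:
    """Shape of a generated subsumption DAG; the deep-taxonomy preset
    mirrors the largest observed deployment (~16,000 classes)."""

    n_classes: int = 2000
    max_depth: int = 8
    branching: int = 5
    multiparent_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1:
            raise OntoRegistryError("n_classes must be positive")
        if not 0 <= self.multiparent_fraction <= 1:
            raise OntoRegistryError("multiparent_fraction outside [0, 1]")


# widget plan cycled across generated fields: (widget, value kind)
_WIDGET_PLAN = (
    ("SingleCell", "string"),
    ("SingleCell", "integer"),
    ("Combobox", "options"),
    ("Checkbox", "boolean"),
    ("SingleCell", "float"),
    ("RadioButton", "coded"),
    ("MultilineStringProperty", "string"),
    ("SingleCell", "date"),
    ("Password", "string"),
    ("HyperlinkProperty", "string"),
    ("SingleCell", "datetime"),
    ("Graphic", "string"),
    ("LiteralProperty", None),
    ("ImageProperty", "string"),
)

_XSD_OF = {
    "string": XSD_NS + "string",
    "integer": XSD_NS + "integer",
    "float": XSD_NS + "double",
    "boolean": XSD_NS + "boolean",
    "date": XSD_NS + "date",
    "datetime": XSD_NS + "dateTime",
}


def generate_registry(params: RegistryParams | None = None, **kw) -> StatementSet:
    """Generate an application ontology that validates with zero errors.

    The layout mirrors a clinical registry: a ``Case`` root form plus
    satellite forms reachable through menu object properties, a fraction of
    which are dependent (cascade on case deletion) and reportable (notify
    on creation).  Field widgets cycle through the whole vocabulary, so
    every widget kind and facet appears under default parameters.
    """
    if params is None:
        params = RegistryParams(**kw)
    rng = random.Random(params.seed)
    ns = params.namespace
    ontology_iri = ns[:-1]
    s: list[Statement] = []

    def add(subject, predicate, obj):
        s.append(Statement(subject, predicate, obj, ns))

    def flag(prop, facet, value="true"):
        add(prop, facet, Literal(value, "boolean"))

    add(ontology_iri, RDF_TYPE, OWL_ONTOLOGY)
    add(ontology_iri, OWL_IMPORTS, mm.MM_ONTOLOGY_IRI)
    app_cls = ns + "App"
    add(app_cls, RDF_TYPE, mm.APPLICATION)
    add(app_cls, RDF_TYPE, OWL_CLASS)

    structures = [ns + "Case"] + [
        ns + f"Form{i:02d}" for i in range(1, params.n_data_structures)
    ]
    n_rep = round(params.reportable_fraction * (len(structures) - 1))
    n_dep = round(params.dependent_fraction * (len(structures) - 1))
    reportable = set(structures[1 : 1 + n_rep])
    dependent = set(rng.sample(structures[1:], n_dep)) if n_dep else set()

    for ds in structures:
        add(ds, RDF_TYPE, mm.DATA_STRUCTURE)
        add(ds, RDF_TYPE, OWL_CLASS)
        add(ds, RDFS_SUBCLASSOF, mm.APPLICATION_ITEM)
        if ds in reportable:
            add(ds, RDFS_SUBCLASSOF, mm.REPORTABLE)

    for ds in structures[1:]:
        prop = ns + "has" + local_name(ds)
        add(prop, RDF_TYPE, OWL_OBJECT_PROPERTY)
        add(prop, RDF_TYPE, mm.MENU_ITEM)
        add(prop, RDFS_DOMAIN, structures[0])
        add(prop, RDFS_RANGE, ds)
        if ds in dependent:
            flag(prop, mm.WEB_DIRECTLY_DEPENDENT)

    widget_cycle = 0
    for ds in structures:
        ds_local = local_name(ds)
        lo, hi = params.fields_per_structure
        n_fields = rng.randint(lo, hi)
        # field 1 is always the id field
        fid = ns + f"{ds_local}_id"
        add(fid, RDF_TYPE, OWL_DATATYPE_PROPERTY)
        add(fid, RDF_TYPE, mm.WIDGET_IRIS["SingleCell"])
        add(fid, RDFS_DOMAIN, ds)
        add(fid, RDFS_RANGE, _XSD_OF["string"])
        add(fid, mm.WEB_ROW, Literal("1", "integer"))
        add(fid, mm.WEB_COLUMN, Literal("1", "integer"))
        flag(fid, mm.WEB_ID)
        flag(fid, mm.WEB_MANDATORY)
        flag(fid, mm.WEB_DESCRIPTION)
        for j in range(2, n_fields + 1):
            widget, kind = _WIDGET_PLAN[widget_cycle % len(_WIDGET_PLAN)]
            widget_cycle += 1
            prop = ns + f"{ds_local}_f{j:02d}"
            is_object = kind in ("options", "coded")
            add(
                prop,
                RDF_TYPE,
                OWL_OBJECT_PROPERTY if is_object else OWL_DATATYPE_PROPERTY,
            )
            add(prop, RDF_TYPE, mm.WIDGET_IRIS[widget])
            add(prop, RDFS_DOMAIN, ds)
            add(prop, mm.WEB_ROW, Literal(str(j), "integer"))
            add(prop, mm.WEB_COLUMN, Literal("1", "integer"))
            if is_object:
                coded = kind == "coded" or rng.random() < 0.5
                list_cls = prop + "_Options"
                add(list_cls, RDF_TYPE, OWL_CLASS)
                add(
                    list_cls,
                    RDFS_SUBCLASSOF,
                    mm.CODED_VALUES if coded else mm.ALLOWED_VALUES,
                )
                add(prop, RDFS_RANGE, list_cls)
                for k in range(1, rng.randint(3, 5) + 1):
                    opt = list_cls + f"_{k}"
                    add(opt, RDF_TYPE, list_cls)
                    add(opt, mm.ITEM_ORDER, Literal(str(k), "integer"))
                    if coded:
                        add(opt, mm.CODE, Literal(f"C{k:02d}", "string"))
            elif kind is None:  # LiteralProperty: display only, no value
                add(prop, RDFS_RANGE, _XSD_OF["string"])
            else:
                add(prop, RDFS_RANGE, _XSD_OF[kind])
            if j == 2:
                flag(prop, mm.WEB_DESCRIPTION)
            if kind not in (None,) and widget != "Password" and rng.random() < 0.3:
                flag(prop, mm.WEB_MANDATORY)
            if kind == "string" and widget == "SingleCell" and rng.random() < 0.1:
                flag(prop, mm.WEB_EDITION_DISABLED)

    # one SubForm field on the case root: validators warn, compilers skip
    sub = ns + "Case_subform"
    add(sub, RDF_TYPE, OWL_DATATYPE_PROPERTY)
    add(sub, RDF_TYPE, mm.WIDGET_IRIS["SubForm"])
    add(sub, RDFS_DOMAIN, structures[0])
    add(sub, RDFS_RANGE, _XSD_OF["string"])
    add(sub, mm.WEB_ROW, Literal("99", "integer"))
    add(sub, mm.WEB_COLUMN, Literal("1", "integer"))

    # extraction specifications: the case recursively, every form flat
    ext = ns + "extract_Case_recursive"
    add(ext, RDF_TYPE, mm.DATA_EXTRACTION)
    add(ext, mm.EXTRACTION_TARGET, structures[0])
    add(ext, mm.EXTRACTION_RECURSIVE, Literal("true", "boolean"))
    for ds in structures:
        ext = ns + "extract_" + local_name(ds)
        add(ext, RDF_TYPE, mm.DATA_EXTRACTION)
        add(ext, mm.EXTRACTION_TARGET, ds)
        add(ext, mm.EXTRACTION_RECURSIVE, Literal("false", "boolean"))

    return StatementSet.from_statements(s, origin_ns=ns)


def caps_registry(name: str = "caps") -> StatementSet:
    """A small, fixed registry modeled on a catastrophic antiphospholipid
    syndrome (CAPS) case registry: a clinical-case root with previous
    manifestations, precipitating factors, clinical manifestations,
    laboratory results and treatment forms."""
    ns = f"https://example.org/registry/{name}#"
    ontology_iri = ns[:-1]
    s = []

    def add(subject, predicate, obj):
        s.append(Statement(subject, predicate, obj, ns))

    def lit(v, tag="string"):
        return Literal(str(v), tag)

    def facet_true(prop, facet):
        add(prop, facet, lit("true", "boolean"))

    add(ontology_iri, RDF_TYPE, OWL_ONTOLOGY)
    add(ontology_iri, OWL_IMPORTS, mm.MM_ONTOLOGY_IRI)
    add(ns + "CAPS", RDF_TYPE, mm.APPLICATION)
    add(ns + "CAPS", RDF_TYPE, OWL_CLASS)

    case = ns + "case"
    satellites = [
        ns + "Previous_Manifestations",
        ns + "Precipitating_Factors",
        ns + "Clinical_Manifestations",
        ns + "laboratory",
        ns + "treatment",
    ]
    for ds in [case] + satellites:
        add(ds, RDF_TYPE, mm.DATA_STRUCTURE)
        add(ds, RDF_TYPE, OWL_CLASS)
        add(ds, RDFS_SUBCLASSOF, mm.APPLICATION_ITEM)
    # adverse clinical manifestations are notified on creation
    add(ns + "Clinical_Manifestations", RDFS_SUBCLASSOF, mm.REPORTABLE)

    for ds in satellites:
        prop = ns + "has_" + local_name(ds)
        add(prop, RDF_TYPE, OWL_OBJECT_PROPERTY)
        add(prop, RDF_TYPE, mm.MENU_ITEM)
        add(prop, RDFS_DOMAIN, case)
        add(prop, RDFS_RANGE, ds)
    # laboratory results cannot exist without their case
    facet_true(ns + "has_laboratory", mm.WEB_DIRECTLY_DEPENDENT)

    def field(ds, local, widget, rng_iri, row, col, **facets):
        prop = ns + local
        is_object = not rng_iri.startswith(XSD_NS)
        add(
            prop,
            RDF_TYPE,
            OWL_OBJECT_PROPERTY if is_object else OWL_DATATYPE_PROPERTY,
        )
        add(prop, RDF_TYPE, mm.WIDGET_IRIS[widget])
        add(prop, RDFS_DOMAIN, ds)
        add(prop, RDFS_RANGE, rng_iri)
        add(prop, mm.WEB_ROW, lit(row, "integer"))
        add(prop, mm.WEB_COLUMN, lit(col, "integer"))
        for facet, on in facets.items():
            if on:
                facet_true(prop, getattr(mm, facet))
        return prop

    def option_list(local, coded, *option_names):
        cls = ns + local
        add(cls, RDF_TYPE, OWL_CLASS)
        add(cls, RDFS_SUBCLASSOF, mm.CODED_VALUES if coded else mm.ALLOWED_VALUES)
        for k, opt_name in enumerate(option_names, 1):
            opt = ns + opt_name
            add(opt, RDF_TYPE, cls)
            add(opt, mm.ITEM_ORDER, lit(k, "integer"))
            if coded:
                add(opt, mm.CODE, lit(f"{local[:3].upper()}{k}"))
        return cls

    sex_list = option_list("SexOptions", True, "Male", "Female")
    organ_list = option_list(
        "OrganOptions", False, "Kidney", "Heart", "Lung", "Brain", "Skin"
    )
    factor_list = option_list(
        "FactorOptions", False, "Infection", "Surgery", "Malignancy"
    )

    field(case, "case_id", "SingleCell", _XSD_OF["string"], 1, 1,
          WEB_ID=True, WEB_MANDATORY=True, WEB_DESCRIPTION=True)
    field(case, "first_name", "SingleCell", _XSD_OF["string"], 2, 1,
          WEB_DESCRIPTION=True)
    field(case, "age", "SingleCell", _XSD_OF["integer"], 2, 2)
    field(case, "sex", "RadioButton", sex_list, 3, 1, WEB_MANDATORY=True)
    field(case, "date_of_diagnosis", "SingleCell", _XSD_OF["date"], 3, 2)
    field(case, "access_code", "Password", _XSD_OF["string"], 4, 1)
    field(case, "record_locked", "Checkbox", _XSD_OF["boolean"], 4, 2)
    field(case, "registry_number", "SingleCell", _XSD_OF["string"], 5, 1,
          WEB_EDITION_DISABLED=True)

    field(ns + "Previous_Manifestations", "pm_id", "SingleCell",
          _XSD_OF["string"], 1, 1, WEB_ID=True, WEB_DESCRIPTION=True)
    field(ns + "Previous_Manifestations", "manifestation", "MultilineStringProperty",
          _XSD_OF["string"], 2, 1, WEB_MANDATORY=True)
    field(ns + "Previous_Manifestations", "onset", "SingleCell",
          _XSD_OF["date"], 3, 1)

    field(ns + "Precipitating_Factors", "pf_id", "SingleCell",
          _XSD_OF["string"], 1, 1, WEB_ID=True, WEB_DESCRIPTION=True)
    field(ns + "Precipitating_Factors", "factor", "Combobox", factor_list, 2, 1,
          WEB_MANDATORY=True)

    field(ns + "Clinical_Manifestations", "cm_id", "SingleCell",
          _XSD_OF["string"], 1, 1, WEB_ID=True, WEB_DESCRIPTION=True)
    field(ns + "Clinical_Manifestations", "organ", "Combobox", organ_list, 2, 1,
          WEB_MANDATORY=True)
    field(ns + "Clinical_Manifestations", "severity", "SingleCell",
          _XSD_OF["integer"], 3, 1)

    field(ns + "laboratory", "test_name", "SingleCell", _XSD_OF["string"], 1, 1,
          WEB_ID=True, WEB_DESCRIPTION=True, WEB_MANDATORY=True)
    field(ns + "laboratory", "result_value", "SingleCell", _XSD_OF["float"], 2, 1)
    field(ns + "laboratory", "unit", "SingleCell", _XSD_OF["string"], 2, 2)

    field(ns + "treatment", "drug", "SingleCell", _XSD_OF["string"], 1, 1,
          WEB_ID=True, WEB_DESCRIPTION=True, WEB_MANDATORY=True)
    field(ns + "treatment", "dose_mg", "SingleCell", _XSD_OF["float"], 2, 1)
    field(ns + "treatment", "notes", "MultilineStringProperty",
          _XSD_OF["string"], 3, 1)

    add(ns + "extract_case", RDF_TYPE, mm.DATA_EXTRACTION)
    add(ns + "extract_case", mm.EXTRACTION_TARGET, case)
    add(ns + "extract_case", mm.EXTRACTION_RECURSIVE, lit("true", "boolean"))
    add(ns + "extract_laboratory", RDF_TYPE, mm.DATA_EXTRACTION)
    add(ns + "extract_laboratory", mm.EXTRACTION_TARGET, ns + "laboratory")
    add(ns + "extract_laboratory", mm.EXTRACTION_RECURSIVE, lit("false", "boolean"))

    return StatementSet.from_statements(s, origin_ns=ns)


# ---------------------------------------------------------------------------
# hierarchies


def generate_hierarchy(params: HierarchyParams | None = None, **kw):
    """Random acyclic subsumption edge set over resources 1..n.

    Built as a rooted tree honoring ``max_depth`` and ``branching``, then a
    ``multiparent_fraction`` of non-root nodes receive one extra parent
    (always an earlier node, so the result stays acyclic).
    """
    if params is None:
        params = HierarchyParams(**kw)
    rng = random.Random(params.seed)
    n = params.n_classes
    edges = []
    depth = {1: 0}
    children = {1: 0}
    for i in range(2, n + 1):
        eligible = [
            k
            for k in range(1, i)
            if depth[k] < params.max_depth and children[k] < params.branching
        ]
        if not eligible:
            eligible = [k for k in range(1, i) if depth[k] < params.max_depth]
        if not eligible:
            eligible = list(range(1, i))
        parent = rng.choice(eligible)
        edges.append(hmod.SubsumptionEdge(i, parent))
        depth[i] = depth[parent] + 1
        children[i] = 0
        children[parent] += 1
    extra = round(params.multiparent_fraction * max(0, n - 1))
    candidates = [i for i in range(2, n + 1)]
    rng.shuffle(candidates)
    primary = {e.child: e.parent for e in edges}
    added = 0
    for i in candidates:
        if added >= extra:
            break
        pool = [k for k in range(1, i) if k != primary[i]]
        if not pool:
            continue
        edges.append(hmod.SubsumptionEdge(i, rng.choice(pool)))
        added += 1
    return set(edges)


def hierarchy_ontology(
    params: HierarchyParams | None = None, ns: str | None = None, **kw
) -> StatementSet:
    """Turn a generated hierarchy into an OWL class taxonomy ontology."""
    if params is None:
        params = HierarchyParams(**kw)
    edges = generate_hierarchy(params)
    if ns is None:
        ns = f"https://example.org/taxonomy/t{params.seed:04d}#"
    s = [Statement(ns[:-1], RDF_TYPE, OWL_ONTOLOGY, ns)]
    nodes = {1} | {e.child for e in edges} | {e.parent for e in edges}
    for i in sorted(nodes):
        s.append(Statement(f"{ns}C{i:05d}", RDF_TYPE, OWL_CLASS, ns))
    for e in sorted(edges, key=lambda e: (e.child, e.parent)):
        s.append(
            Statement(
                f"{ns}C{e.child:05d}", RDFS_SUBCLASSOF, f"{ns}C{e.parent:05d}", ns
            )
        )
    return StatementSet.from_statements(s, origin_ns=ns)


def bulk_ontology(n_statements: int = 100_000, seed: int = 0) -> StatementSet:
    """A large mixed ontology (taxonomy + properties + instance data) whose
    statement count approximates ``n_statements``; bulk-ingestion stress
    input at the scale of the largest deployed projects."""
    rng = random.Random(seed)
    ns = f"https://example.org/bulk/b{seed:04d}#"
    s = [Statement(ns[:-1], RDF_TYPE, OWL_ONTOLOGY, ns)]

    n_classes = max(10, n_statements // 25)
    for i in range(1, n_classes + 1):
        s.append(Statement(f"{ns}C{i:05d}", RDF_TYPE, OWL_CLASS, ns))
        if i > 1:
            parent = rng.randint(1, i - 1)
            s.append(
                Statement(
                    f"{ns}C{i:05d}", RDFS_SUBCLASSOF, f"{ns}C{parent:05d}", ns
                )
            )
    props = []
    for i in range(1, 21):
        p = f"{ns}p{i:02d}"
        props.append((p, "integer" if i % 2 else "string"))
        s.append(Statement(p, RDF_TYPE, OWL_DATATYPE_PROPERTY, ns))
        s.append(Statement(p, RDFS_DOMAIN, f"{ns}C00001", ns))
        s.append(Statement(p, RDFS_RANGE, _XSD_OF["integer" if i % 2 else "string"], ns))
    i = 0
    while len(s) < n_statements:
        i += 1
        inst = f"{ns}i{i:06d}"
        s.append(
            Statement(inst, RDF_TYPE, f"{ns}C{rng.randint(1, n_classes):05d}", ns)
        )
        for p, tag in rng.sample(props, 3):
            value = (
                Literal(str(rng.randint(0, 10**6)), "integer")
                if tag == "integer"
                else Literal(f"v{rng.randint(0, 10**6)}", "string")
            )
            s.append(Statement(inst, p, value, ns))
    return StatementSet.from_statements(s, origin_ns=ns)


# ---------------------------------------------------------------------------
# populations


def _field_value(rng: random.Random, spec, ds_local, case_no, child_no):
    start = datetime.date(2015, 1, 1)
    kind = spec.value_type
    if kind == "options":
        return rng.choice(spec.options).iri
    if kind == "integer":
        return rng.randint(0, 120)
    if kind == "float":
        return round(rng.uniform(0, 500), 2)
    if kind == "boolean":
        return rng.random() < 0.5
    if kind == "date":
        return start + datetime.timedelta(days=rng.randint(0, 3000))
    if kind == "datetime":
        return datetime.datetime(2015, 1, 1) + datetime.timedelta(
            minutes=rng.randint(0, 10**6)
        )
    if spec.widget in ("HyperlinkProperty", "Graphic", "ImageProperty"):
        return f"https://files.example.org/{ds_local}/{case_no}_{child_no}.png"
    if spec.widget == "Password":
        return f"secret-{rng.randint(0, 10**6)}"
    return f"text {rng.randint(0, 10**6)}"


def populate_instances(
    repo, app_ns: str, params: RegistryParams | None = None, notify=None, **kw
) -> dict:
    """Create a seeded instance population through the CRUD path.

    Every creation passes the full constraint pipeline (mandatory, id
    uniqueness, option membership, typing), so a successful run leaves a
    repository that a whole-state audit finds clean.  Returns a summary
    with per-structure live counts.
    """
    if params is None:
        params = RegistryParams(**kw)
    rng = random.Random(params.seed + 1)
    registry = Registry(repo, app_ns, notify=notify)
    g = registry.graph
    case_ds = None
    menu_targets = []
    for prop in g.menu_properties():
        domain = g.object(prop, RDFS_DOMAIN)
        target = g.object(prop, RDFS_RANGE)
        case_ds = domain
        menu_targets.append((prop, target))
    if case_ds is None:
        structures = g.data_structures()
        case_ds = structures[0] if structures else None
    created = {ds: 0 for ds in g.data_structures()}

    def build_values(ds, case_no, child_no):
        values = {}
        ds_local = local_name(ds)
        for spec in registry.specs(ds):
            if spec.widget == "LiteralProperty":
                continue
            if spec.facets.is_id:
                values[spec.property_iri] = f"{ds_local}-{case_no:05d}-{child_no}"
            elif spec.facets.is_mandatory or rng.random() < 0.8:
                values[spec.property_iri] = _field_value(
                    rng, spec, ds_local, case_no, child_no
                )
        return values

    lo, hi = params.children_per_structure
    for case_no in range(1, params.n_cases + 1):
        case_values = build_values(case_ds, case_no, 0)
        for prop, target in menu_targets:
            kids = []
            for child_no in range(1, rng.randint(lo, hi) + 1):
                kid = registry.create_instance(
                    target, build_values(target, case_no, child_no)
                )
                created[target] += 1
                kids.append(kid)
            if kids:
                case_values[prop] = kids
        registry.create_instance(case_ds, case_values)
        created[case_ds] += 1
    return {
        "cases": params.n_cases,
        "instances": sum(created.values()),
        "by_structure": created,
    }


# ---------------------------------------------------------------------------
# fault injection


def drop_statement(sset, predicate=None, subject=None, obj=None):
    """Copy of a statement set minus every matching statement."""
    kept = [
        s
        for s in sset.statements
        if not (
            (predicate is None or s.predicate == predicate)
            and (subject is None or s.subject == subject)
            and (obj is None or s.object == obj)
        )
    ]
    if len(kept) == len(sset.statements):
        raise OntoRegistryError("mutation matched no statement")
    return StatementSet.from_statements(kept, origin_ns=sset.origin_ns)


def add_statements(sset, *statements):
    return StatementSet.from_statements(
        list(sset.statements) + list(statements), origin_ns=sset.origin_ns
    )


def validator_mutations(app: StatementSet | None = None) -> dict:
    """One single-mutation faulty fixture per validation rule.

    Operates on the fixed CAPS-like registry; returns {rule code: mutated
    statement set}.  Each mutation is built to trigger exactly its rule,
    which makes the map a completeness oracle for the validator.
    """
    caps = app if app is not None else caps_registry()
    ns = caps.origin_ns

    def lit(v, tag):
        return Literal(str(v), tag)

    out = {}
    out[mm.APP_MISSING] = drop_statement(
        caps, predicate=RDF_TYPE, subject=ns + "CAPS", obj=mm.APPLICATION
    )
    out[mm.FORM_NOT_APPLICATION_ITEM] = drop_statement(
        caps,
        predicate=RDFS_SUBCLASSOF,
        subject=ns + "treatment",
        obj=mm.APPLICATION_ITEM,
    )
    out[mm.FIELD_WIDGET_COUNT] = drop_statement(
        caps,
        predicate=RDF_TYPE,
        subject=ns + "age",
        obj=mm.WIDGET_IRIS["SingleCell"],
    )
    out[mm.MENU_MALFORMED] = add_statements(
        drop_statement(caps, predicate=RDFS_RANGE, subject=ns + "has_treatment"),
        Statement(ns + "has_treatment", RDFS_RANGE, ns + "SexOptions", ns),
    )
    out[mm.GRID_COLLISION] = add_statements(
        drop_statement(caps, predicate=mm.WEB_COLUMN, subject=ns + "age"),
        Statement(ns + "age", mm.WEB_COLUMN, lit(1, "integer"), ns),
    )
    out[mm.OPTIONS_MISSING] = add_statements(
        drop_statement(caps, predicate=RDFS_RANGE, subject=ns + "sex"),
        Statement(ns + "sex", RDFS_RANGE, _XSD_OF["string"], ns),
    )
    out[mm.CODE_MISSING] = drop_statement(
        caps, predicate=mm.CODE, subject=ns + "Male"
    )
    out[mm.ORDER_MISSING] = drop_statement(
        caps, predicate=mm.ITEM_ORDER, subject=ns + "Kidney"
    )
    out[mm.SUBFORM_UNSUPPORTED] = add_statements(
        caps,
        Statement(ns + "extra_subform", RDF_TYPE, OWL_DATATYPE_PROPERTY, ns),
        Statement(ns + "extra_subform", RDF_TYPE, mm.WIDGET_IRIS["SubForm"], ns),
        Statement(ns + "extra_subform", RDFS_DOMAIN, ns + "case", ns),
        Statement(ns + "extra_subform", mm.WEB_ROW, lit(9, "integer"), ns),
        Statement(ns + "extra_subform", mm.WEB_COLUMN, lit(1, "integer"), ns),
    )
    out[mm.DEPENDENT_NOT_OBJECT] = add_statements(
        caps,
        Statement(ns + "age", mm.WEB_DIRECTLY_DEPENDENT, lit("true", "boolean"), ns),
    )
    out[mm.ID_FIELD_DUPLICATE] = add_statements(
        caps,
        Statement(ns + "first_name", mm.WEB_ID, lit("true", "boolean"), ns),
    )
    return out
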