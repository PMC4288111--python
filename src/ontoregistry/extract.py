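"""Data extraction: XML exports, relational SQL mirror, bulk ingestion.

An application declares what to extract as instances of the
``DataExtraction`` class: each names a target data structure and whether
object-property values are traversed recursively (nesting the referenced
records) or emitted as id references.  The second export path mirrors the
whole application into plain relational form — one table per data
structure, one column per datatype field, link tables for object links —
as an executable SQL script snapshot.

The bulk ingestion path (``ontoload``) feeds the statements table
directly: statements are inserted in one batch with structural propagation
deferred, then the structural tables and the hierarchy index are rebuilt
once.  The final repository state is identical to loading the same
ontology statement by statement through the editor path.
"""

from __future__ import annotations

from dataclasses import dataclass

from lxml import etree

from . import store
from .forms import Registry
from .exceptions import (
    NameCollisionError,
    NothingToExtractError,
    ParseError,
)
from .metamodel import DATA_EXTRACTION, EXTRACTION_RECURSIVE, EXTRACTION_TARGET
from .namespaces import RDFS_DOMAIN, local_name
from .owl_core import Literal, parse_owl

EXPORT_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class ExtractionSpec:
    name: str
    target: str  # data-structure (or class) IRI
    recursive: bool


def extraction_specs(registry: Registry) -> list:
    """The DataExtraction instances declared by the application."""
    g = registry.graph
    specs = []
    for inst in sorted(g.instances(DATA_EXTRACTION)):
        target = g.object(inst, EXTRACTION_TARGET)
        rec = g.object(inst, EXTRACTION_RECURSIVE)
        recursive = isinstance(rec, Literal) and rec.lexical.lower() in ("true", "1")
        if target:
            specs.append(ExtractionSpec(local_name(inst), target, recursive))
    return specs


def _password_properties(registry: Registry):
    out = set()
    for ds in registry.graph.data_structures():
        for spec in registry.specs(ds):
            if spec.widget == "Password":
                out.add(spec.property_iri)
    return out


def _menu_props_of(registry: Registry, ds_iri):
    g = registry.graph
    return [
        p for p in g.menu_properties() if g.object(p, RDFS_DOMAIN) == ds_iri
    ]


def _live_instance_ids(registry: Registry, ds_iri):
    return registry.live_instances(ds_iri)


def run_extractions(repo: store.Repository, app_ns: str) -> dict:
    """Execute every extraction spec; returns {name: XML document text}.

    Each document holds one ``record`` element per live instance of the
    target structure.  With recursion, referenced objects are inlined as
    nested records, each instance expanded at most once per document
    (subsequent occurrences, and any cycles, fall back to ``ref``
    attributes).  Deleted instances and password fields never appear.
    """
    registry = Registry(repo, app_ns)
    specs = extraction_specs(registry)
    if not specs:
        raise NothingToExtractError(
            f"application {app_ns} declares no DataExtraction instances"
        )
    passwords = _password_properties(registry)
    docs = {}
    for ext in specs:
        root = etree.Element(
            "extraction",
            attrib={
                "class": ext.target,
                "recursive": "true" if ext.recursive else "false",
                "schema-version": EXPORT_SCHEMA_VERSION,
            },
        )
        for inst in _live_instance_ids(registry, ext.target):
            root.append(
                _record_element(
                    registry, inst, ext.target, ext.recursive, passwords,
                    expanded=set(),
                )
            )
        docs[ext.name] = etree.tostring(
            root, pretty_print=True, xml_declaration=True, encoding="utf-8"
        ).decode("utf-8")
    return docs


def _record_element(registry, inst, ds_iri, recursive, passwords, expanded):
    repo = registry.repo
    expanded.add(inst)
    el = etree.Element(
        "record", attrib={"id": str(inst), "class": local_name(ds_iri)}
    )
    values = store.values_of(repo, inst)
    by_iri = {repo.iri(pid): vals for pid, vals in values.items()}
    option_specs = {}
    field_order = []
    for spec in registry.specs(ds_iri):
        field_order.append(spec.property_iri)
        if spec.value_type == "options":
            option_specs[spec.property_iri] = spec
    link_props = _menu_props_of(registry, ds_iri) + [
        s.property_iri
        for s in registry.specs(ds_iri)
        if s.value_type == "resource"
    ]
    for prop in field_order + [p for p in link_props if p not in field_order]:
        if prop in passwords:
            continue
        vals = by_iri.get(prop, [])
        name = local_name(prop)
        spec = option_specs.get(prop)
        for tag, v in sorted(vals, key=lambda t: str(t[1])):
            if tag != "resource":
                sub = etree.SubElement(el, name)
                sub.text = str(v)
                continue
            target_iri = repo.iri(v)
            if spec is not None:  # coded / plain option value
                sub = etree.SubElement(el, name)
                opt = next((o for o in spec.options if o.iri == target_iri), None)
                sub.text = opt.label if opt else local_name(target_iri)
                if opt is not None and opt.code is not None:
                    sub.set("code", opt.code)
                continue
            child_ds = _data_structure_of(registry, v)
            if child_ds is None:
                continue  # deleted or foreign reference: excluded
            if recursive and v not in expanded:
                sub = etree.SubElement(el, name)
                sub.append(
                    _record_element(
                        registry, v, child_ds, recursive, passwords, expanded
                    )
                )
            else:
                sub = etree.SubElement(el, name)
                sub.set("ref", str(v))
    return el


def _data_structure_of(registry, instance_id):
    repo = registry.repo
    for (cid,) in repo.q(
        "SELECT class_id FROM instances WHERE instance_id = ? AND deleted = 0",
        instance_id,
    ):
        iri = repo.iri(cid)
        if iri in registry.graph.data_structures():
            row = repo.one(
                "SELECT deleted FROM resources WHERE id = ?", instance_id
            )
            if row and not row[0]:
                return iri
    return None


# ---------------------------------------------------------------------------
# relational mirror


_SQL_TYPE = {
    "string": "VARCHAR(4000)",
    "integer": "INTEGER",
    "float": "DOUBLE PRECISION",
    "boolean": "SMALLINT",
    "date": "CHAR(10)",
    "datetime": "VARCHAR(32)",
}


def _mangle(iri: str) -> str:
    name = "".join(
        c if c.isalnum() else "_" for c in local_name(iri).lower()
    )
    return name or "unnamed"


def _qi(name: str) -> str:
    """Quote an SQL identifier (portable, and safe for reserved words)."""
    return '"' + name + '"'


def _sql_quote(value) -> str:
    if value is None:
        return "NULL"
    if isinstance(value, (int, float)):
        return repr(value)
    return "'" + str(value).replace("'", "''") + "'"


def export_sql(repo: store.Repository, app_ns: str) -> str:
    """Mirror the application into an executable SQL script snapshot.

    One table per data structure (primary key = instance id), one column
    per datatype field, option fields as text (label plus a ``_code``
    column for coded lists), and one link table per object property.
    Password fields and soft-deleted instances are never exported.  The
    script is deterministic and one-shot: re-running it on the same
    database fails on the duplicate primary keys.
    """
    registry = Registry(repo, app_ns)
    g = registry.graph
    tables = {}
    for ds in g.data_structures():
        name = _mangle(ds)
        tables.setdefault(name, []).append(ds)
    collisions = {n: ds for n, ds in tables.items() if len(ds) > 1}
    if collisions:
        raise NameCollisionError(
            f"data structures collide after SQL name mangling: {collisions}"
        )
    ddl, dml = [], []
    link_tables = []
    for ds in g.data_structures():
        table = _mangle(ds)
        columns = [("id", "INTEGER PRIMARY KEY")]
        col_specs = []
        seen = {"id"}
        for spec in registry.specs(ds):
            if spec.widget in ("Password", "LiteralProperty"):
                continue
            col = _mangle(spec.property_iri)
            if col in seen:
                raise NameCollisionError(
                    f"column {col!r} duplicated in table {table!r}"
                )
            seen.add(col)
            if spec.value_type == "options":
                columns.append((col, "VARCHAR(4000)"))
                col_specs.append((col, spec, "label"))
                if any(o.code is not None for o in spec.options):
                    columns.append((col + "_code", "VARCHAR(64)"))
                    col_specs.append((col + "_code", spec, "code"))
            elif spec.value_type == "resource":
                link_tables.append((ds, spec.property_iri))
            else:
                columns.append((col, _SQL_TYPE[spec.value_type]))
                col_specs.append((col, spec, "value"))
        for prop in _menu_props_of(registry, ds):
            link_tables.append((ds, prop))
        ddl.append(
            f"CREATE TABLE {_qi(table)} (\n    "
            + ",\n    ".join(f"{_qi(c)} {t}" for c, t in columns)
            + "\n);"
        )
        col_names = [c for c, _ in columns]
        for inst in registry.live_instances(ds):
            values = store.values_of(repo, inst)
            by_iri = {repo.iri(pid): v for pid, v in values.items()}
            row = {"id": inst}
            for col, spec, role in col_specs:
                vals = by_iri.get(spec.property_iri, [])
                if not vals:
                    continue
                tag, v = vals[0]
                if role in ("label", "code"):
                    if tag != "resource":
                        continue
                    opt_iri = repo.iri(v)
                    opt = next(
                        (o for o in spec.options if o.iri == opt_iri), None
                    )
                    if opt is None:
                        continue
                    row[col] = opt.label if role == "label" else opt.code
                else:
                    row[col] = v
            dml.append(
                f"INSERT INTO {_qi(table)} "
                f"({', '.join(_qi(c) for c in col_names if c in row)}) "
                f"VALUES ({', '.join(_sql_quote(row[c]) for c in col_names if c in row)});"
            )
    for ds, prop in sorted(set(link_tables)):
        parent = _mangle(ds)
        link = f"{parent}_{_mangle(prop)}"
        parent_col = _qi(parent + "_id")
        ddl.append(
            f"CREATE TABLE {_qi(link)} (\n    {parent_col} INTEGER,\n    "
            f"target_id INTEGER,\n    PRIMARY KEY ({parent_col}, target_id)\n);"
        )
        prop_id = repo.resource_id(prop)
        for inst in registry.live_instances(ds):
            for tag, v in store.values_of(repo, inst).get(prop_id, []):
                if tag != "resource":
                    continue
                if _data_structure_of(registry, v) is None:
                    continue
                dml.append(
                    f"INSERT INTO {_qi(link)} ({parent_col}, target_id) "
                    f"VALUES ({inst}, {v});"
                )
    header = [
        "-- relational mirror of application " + app_ns,
        "-- schema-version " + EXPORT_SCHEMA_VERSION,
    ]
    return "\n".join(header + ddl + dml) + "\n"


# ---------------------------------------------------------------------------
# bulk ingestion


def ontoload(
    repo: store.Repository, document: str, dialect: str = "rdfxml"
) -> dict:
    """Bulk-load an OWL document by feeding the statements table directly.

    All statements are inserted in one transaction with propagation
    deferred; the structural tables are then rebuilt from the statements
    table in one pass and the hierarchy index in one batch.  On any parse
    failure nothing is persisted.  The resulting repository state is
    identical to a statement-by-statement upload of the same document.
    """
    sset = parse_owl(document, dialect)
    if len(sset) == 0:
        raise ParseError("document contains no statements; nothing to load")
    ns, prepared = store._prepare_statements(sset)
    store._register_ontology(repo, ns, sset)
    inserted = 0
    with repo.tx():
        rows = []
        for s in prepared:
            s_id = repo.rid(s.subject, ns)
            p_id = repo.rid(s.predicate, ns)
            kind, o_id, lex, dtag = repo._object_descriptor(s.object)
            existing = repo.find_statement(s)
            if existing is not None:
                if existing[1]:
                    repo.q(
                        "UPDATE statements SET deleted = 0 WHERE id = ?",
                        existing[0],
                    )
                continue
            rows.append((s_id, p_id, o_id, lex, dtag, kind, ns))
        repo.conn.executemany(
            "INSERT INTO statements(subject_id, predicate_id, object_id, "
            "object_lexical, object_datatype, object_kind, ontology_ns, deleted) "
            "VALUES(?, ?, ?, ?, ?, ?, ?, 0)",
            rows,
        )
        inserted = len(rows)
        target = store.rebuild_structural(repo)
        store.apply_structural_state(repo, target)
    repo.rebuild_hierarchy()
    return {"namespace": ns, "statements": inserted, "ontology": sset.ontology_iri}
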