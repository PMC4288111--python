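"""Relational persistence of ontologies and instance data.

The repository follows a hybrid storage scheme: one table per
ontology-language metaclass role (resource, class, property, domain, range,
subsumption, instance-of) plus one value table per supported literal
datatype and one for resource-valued property instances.  A single
statements table stores every asserted triple and acts as the interface:
adding or deleting a statement propagates, inside the same transaction, to
the structural tables, so that at any point the structural tables equal
what a from-scratch rebuild over the live statements would produce.  (The
original design used database triggers; here propagation is application
level with identical observable semantics.)

Resources are identified by short surrogate integer ids rather than full
IRIs; ids are never reused.  Nothing is ever physically deleted — every
table carries a ``deleted`` flag, so the total physical row count is
monotonically non-decreasing under any API call.

Transitive queries (subclasses, instances at any depth) are answered
through a nested-set interval index over the subsumption tables (see
:mod:`ontoregistry.hierarchy`), rebuilt in one batch pass after bulk loads
rather than per inserted class.
"""

from __future__ import annotations

import hashlib
import sqlite3
from contextlib import contextmanager
from dataclasses import dataclass, field as dfield

from . import hierarchy as hmod
from . import metamodel as mm
from .exceptions import (
    ContradictoryTypingError,
    GuardViolationError,
    NameCollisionError,
    SchemaError,
    UnknownResourceError,
)
from .namespaces import (
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
)
from .owl_core import (
    Literal,
    Statement,
    StatementSet,
    import_closure,
    is_blank,
    ontology_ns,
)

SCHEMA_VERSION = "1"

VALUE_TABLES = {
    "string": ("values_string", "TEXT"),
    "integer": ("values_integer", "INTEGER"),
    "float": ("values_float", "REAL"),
    "boolean": ("values_boolean", "INTEGER"),
    "date": ("values_date", "TEXT"),
    "datetime": ("values_datetime", "TEXT"),
    "resource": ("values_resource", "INTEGER"),
}

REQUIRED_TABLES = (
    "meta",
    "resources",
    "statements",
    "classes",
    "properties",
    "domains",
    "ranges",
    "subsumption",
    "instances",
    "imports",
    "ontologies",
    "hierarchy_index",
    "notifications",
    "counters",
) + tuple(t for t, _ in VALUE_TABLES.values())

_PROPERTY_TYPE_KIND = {
    OWL_OBJECT_PROPERTY: "object",
    OWL_DATATYPE_PROPERTY: "datatype",
    OWL_ANNOTATION_PROPERTY: "annotation",
}
_CLASS_TYPES = (OWL_CLASS, RDFS_CLASS)

_DDL = """
CREATE TABLE meta(key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE resources(
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    iri TEXT UNIQUE NOT NULL,
    kind TEXT,
    ontology_ns TEXT NOT NULL DEFAULT '',
    deprecated INTEGER NOT NULL DEFAULT 0,
    deleted INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE statements(
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    subject_id INTEGER NOT NULL,
    predicate_id INTEGER NOT NULL,
    object_id INTEGER,
    object_lexical TEXT,
    object_datatype TEXT,
    object_kind TEXT NOT NULL,
    ontology_ns TEXT NOT NULL,
    deleted INTEGER NOT NULL DEFAULT 0
);
CREATE UNIQUE INDEX uq_statements ON statements(
    subject_id, predicate_id, object_kind,
    ifnull(object_id, -1), ifnull(object_lexical, ''),
    ifnull(object_datatype, ''), ontology_ns
);
CREATE INDEX ix_statements_subject ON statements(subject_id);
CREATE INDEX ix_statements_predicate ON statements(predicate_id);
CREATE INDEX ix_statements_object ON statements(object_id);
CREATE TABLE classes(resource_id INTEGER PRIMARY KEY,
                     deleted INTEGER NOT NULL DEFAULT 0);
CREATE TABLE properties(resource_id INTEGER PRIMARY KEY, kind TEXT,
                        deleted INTEGER NOT NULL DEFAULT 0);
CREATE TABLE domains(property_id INTEGER, class_id INTEGER,
                     deleted INTEGER NOT NULL DEFAULT 0,
                     PRIMARY KEY(property_id, class_id));
CREATE TABLE ranges(property_id INTEGER, range_kind TEXT, range_ref TEXT,
                    deleted INTEGER NOT NULL DEFAULT 0,
                    PRIMARY KEY(property_id, range_kind, range_ref));
CREATE TABLE subsumption(child_id INTEGER, parent_id INTEGER, kind TEXT,
                         deleted INTEGER NOT NULL DEFAULT 0,
                         PRIMARY KEY(child_id, parent_id, kind));
CREATE TABLE instances(instance_id INTEGER, class_id INTEGER,
                       deleted INTEGER NOT NULL DEFAULT 0,
                       PRIMARY KEY(instance_id, class_id));
CREATE TABLE imports(importer TEXT, imported TEXT,
                     deleted INTEGER NOT NULL DEFAULT 0,
                     PRIMARY KEY(importer, imported));
CREATE TABLE ontologies(ns TEXT PRIMARY KEY, iri TEXT,
                        deleted INTEGER NOT NULL DEFAULT 0);
CREATE TABLE hierarchy_index(node_id INTEGER, resource_id INTEGER,
                             lft INTEGER, rgt INTEGER, kind TEXT);
CREATE INDEX ix_hier ON hierarchy_index(kind, resource_id);
CREATE INDEX ix_hier_lft ON hierarchy_index(kind, lft);
CREATE TABLE notifications(
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    data_structure_id INTEGER, instance_id INTEGER, created_at TEXT);
CREATE TABLE counters(name TEXT PRIMARY KEY, value INTEGER);
"""

_VALUE_DDL = """
CREATE TABLE {table}(instance_id INTEGER, property_id INTEGER, value {sqltype},
                     deleted INTEGER NOT NULL DEFAULT 0,
                     PRIMARY KEY(instance_id, property_id, value));
CREATE INDEX ix_{table}_prop ON {table}(property_id);
"""


@dataclass
class PropagationEffect:
    """Summary of the rows touched by one statement-level mutation."""

    inserted: dict = dfield(default_factory=dict)  # table -> count
    revived: dict = dfield(default_factory=dict)
    flagged: dict = dfield(default_factory=dict)
    warnings: list = dfield(default_factory=list)

    def count(self, bucket, table, n=1):
        if n:
            d = getattr(self, bucket)
            d[table] = d.get(table, 0) + n

    @property
    def is_noop(self):
        return not (self.inserted or self.revived or self.flagged)


class Repository:
    """Handle over an embedded single-file (or in-memory) SQL repository."""

    def __init__(self, conn: sqlite3.Connection, location: str):
        self.conn = conn
        self.location = location
        self._rid_cache: dict[str, int] = {}
        self._hierarchy_stale = {"class": True, "property": True}
        self._tx_depth = 0

    # -- plumbing ----------------------------------------------------------

    @contextmanager
    def tx(self):
        """Nested-aware transaction; rolls back everything on error."""
        if self._tx_depth == 0:
            self.conn.execute("BEGIN")
        self._tx_depth += 1
        try:
            yield
        except Exception:
            self._tx_depth -= 1
            if self._tx_depth == 0:
                self.conn.execute("ROLLBACK")
                self._rid_cache.clear()
            raise
        else:
            self._tx_depth -= 1
            if self._tx_depth == 0:
                self.conn.execute("COMMIT")

    def q(self, sql, *params):
        return self.conn.execute(sql, params)

    def one(self, sql, *params):
        return self.conn.execute(sql, params).fetchone()

    def close(self):
        self.conn.close()

    def next_counter(self, name: str) -> int:
        self.q(
            "INSERT INTO counters(name, value) VALUES(?, 0) "
            "ON CONFLICT(name) DO NOTHING",
            name,
        )
        self.q("UPDATE counters SET value = value + 1 WHERE name = ?", name)
        return self.one("SELECT value FROM counters WHERE name = ?", name)[0]

    # -- resources ---------------------------------------------------------

    def rid(self, iri: str, ns: str = "", create: bool = True) -> int:
        """Surrogate id for an IRI (or blank label); created on first use."""
        cached = self._rid_cache.get(iri)
        if cached is not None:
            return cached
        row = self.one("SELECT id FROM resources WHERE iri = ?", iri)
        if row is None:
            if not create:
                raise UnknownResourceError(f"unknown resource {iri}")
            cur = self.q(
                "INSERT INTO resources(iri, ontology_ns) VALUES(?, ?)", iri, ns
            )
            rid = cur.lastrowid
        else:
            rid = row[0]
        self._rid_cache[iri] = rid
        return rid

    def iri(self, rid: int) -> str:
        row = self.one("SELECT iri FROM resources WHERE id = ?", rid)
        if row is None:
            raise UnknownResourceError(f"unknown resource id {rid}")
        return row[0]

    def resource_id(self, iri: str) -> int:
        row = self.one(
            "SELECT id FROM resources WHERE iri = ? AND deleted = 0", iri
        )
        if row is None:
            raise UnknownResourceError(f"unknown or deleted resource {iri}")
        return row[0]

    def set_kind(self, rid: int, kind: str):
        self.q("UPDATE resources SET kind = ? WHERE id = ?", kind, rid)

    def deprecate(self, iri: str, flag: bool = True):
        """Set the deprecated flag on a class/property resource."""
        rid = self.resource_id(iri)
        with self.tx():
            self.q(
                "UPDATE resources SET deprecated = ? WHERE id = ?",
                1 if flag else 0,
                rid,
            )

    def is_deprecated(self, iri: str) -> bool:
        row = self.one("SELECT deprecated FROM resources WHERE iri = ?", iri)
        return bool(row and row[0])

    def _mentioned(self, rid: int) -> bool:
        return (
            self.one(
                "SELECT 1 FROM statements WHERE deleted = 0 AND "
                "(subject_id = ? OR predicate_id = ? OR object_id = ?) LIMIT 1",
                rid,
                rid,
                rid,
            )
            is not None
        )

    def _set_resource_deleted(self, rid: int, deleted: bool):
        self.q(
            "UPDATE resources SET deleted = ? WHERE id = ?",
            1 if deleted else 0,
            rid,
        )

    # -- row helpers (insert-or-revive / flag) ------------------------------

    def _upsert(self, effect, table, key_cols, key_vals, extra_cols=(), extra_vals=()):
        cols = list(key_cols) + list(extra_cols)
        vals = list(key_vals) + list(extra_vals)
        where = " AND ".join(f"{c} = ?" for c in key_cols)
        row = self.one(
            f"SELECT deleted FROM {table} WHERE {where}", *key_vals
        )
        if row is None:
            placeholders = ", ".join("?" for _ in cols)
            self.q(
                f"INSERT INTO {table}({', '.join(cols)}, deleted) "
                f"VALUES({placeholders}, 0)",
                *vals,
            )
            effect.count("inserted", table)
        else:
            sets = ["deleted = 0"] + [f"{c} = ?" for c in extra_cols]
            self.q(
                f"UPDATE {table} SET {', '.join(sets)} WHERE {where}",
                *(list(extra_vals) + list(key_vals)),
            )
            if row[0]:
                effect.count("revived", table)

    def _flag(self, effect, table, key_cols, key_vals):
        where = " AND ".join(f"{c} = ?" for c in key_cols)
        cur = self.q(
            f"UPDATE {table} SET deleted = 1 WHERE {where} AND deleted = 0",
            *key_vals,
        )
        effect.count("flagged", table, cur.rowcount)

    # -- hierarchy ---------------------------------------------------------

    def mark_hierarchy_stale(self, kind: str):
        self._hierarchy_stale[kind] = True

    def rebuild_hierarchy(self, kind: str | None = None):
        """One batch nested-set build over the live subsumption rows."""
        kinds = [kind] if kind else ["class", "property"]
        with self.tx():
            for k in kinds:
                edges = [
                    hmod.SubsumptionEdge(c, p)
                    for c, p in self.q(
                        "SELECT child_id, parent_id FROM subsumption "
                        "WHERE kind = ? AND deleted = 0",
                        k,
                    )
                ]
                members = set()
                if k == "class":
                    members = {
                        r for (r,) in self.q(
                            "SELECT resource_id FROM classes WHERE deleted = 0"
                        )
                    }
                else:
                    members = {
                        r for (r,) in self.q(
                            "SELECT resource_id FROM properties WHERE deleted = 0"
                        )
                    }
                with_parents = {e.child for e in edges}
                roots = (members | {e.parent for e in edges}) - with_parents
                index = hmod.build_nested_set(edges, roots)
                self.q("DELETE FROM hierarchy_index WHERE kind = ?", k)
                self.conn.executemany(
                    "INSERT INTO hierarchy_index(node_id, resource_id, lft, rgt, kind)"
                    " VALUES(?, ?, ?, ?, ?)",
                    [
                        (p.node_id, p.resource, p.left, p.right, k)
                        for p in index.nodes
                    ],
                )
                self._hierarchy_stale[k] = False

    def _ensure_hierarchy(self, kind: str):
        if self._hierarchy_stale[kind]:
            self.rebuild_hierarchy(kind)

    # ----------------------------------------------------------------------
    # statement-level interface

    def _object_descriptor(self, obj):
        if isinstance(obj, Literal):
            return ("literal", None, obj.lexical, obj.datatype)
        return ("resource", self.rid(obj), None, None)

    def find_statement(self, stmt: Statement):
        """Physical row (id, deleted) of a statement, or None."""
        s_id = self._rid_cache.get(stmt.subject) or self.one(
            "SELECT id FROM resources WHERE iri = ?", stmt.subject
        )
        if s_id is None:
            return None
        if not isinstance(s_id, int):
            s_id = s_id[0]
        p_row = self.one("SELECT id FROM resources WHERE iri = ?", stmt.predicate)
        if p_row is None:
            return None
        if isinstance(stmt.object, Literal):
            return self.one(
                "SELECT id, deleted FROM statements WHERE subject_id = ? AND "
                "predicate_id = ? AND object_kind = 'literal' AND "
                "object_lexical = ? AND object_datatype = ? AND ontology_ns = ?",
                s_id,
                p_row[0],
                stmt.object.lexical,
                stmt.object.datatype,
                stmt.origin_ns,
            )
        o_row = self.one("SELECT id FROM resources WHERE iri = ?", stmt.object)
        if o_row is None:
            return None
        return self.one(
            "SELECT id, deleted FROM statements WHERE subject_id = ? AND "
            "predicate_id = ? AND object_kind = 'resource' AND object_id = ? "
            "AND ontology_ns = ?",
            s_id,
            p_row[0],
            o_row[0],
            stmt.origin_ns,
        )


def init_repository(target: str = ":memory:") -> Repository:
    """Create (or open) a repository; the metamodel is pre-loaded.

    Idempotent: opening an existing repository validates the schema version
    and the presence of every required table, refusing corrupted or
    incompatible targets.
    """
    conn = sqlite3.connect(target)
    conn.isolation_level = None
    conn.execute("PRAGMA synchronous = OFF")
    conn.execute("PRAGMA journal_mode = MEMORY")
    repo = Repository(conn, target)
    existing = {
        r[0]
        for r in conn.execute(
            "SELECT name FROM sqlite_master WHERE type = 'table'"
        )
    }
    if existing:
        missing = [t for t in REQUIRED_TABLES if t not in existing]
        if missing:
            raise SchemaError(
                f"target {target!r} holds an incompatible or corrupted schema: "
                f"missing tables {missing}"
            )
        row = conn.execute(
            "SELECT value FROM meta WHERE key = 'schema_version'"
        ).fetchone()
        if row is None or row[0] != SCHEMA_VERSION:
            raise SchemaError(
                f"schema version {row[0] if row else None!r} incompatible with "
                f"{SCHEMA_VERSION!r}; migrate the repository first"
            )
        repo._hierarchy_stale = {"class": True, "property": True}
        return repo
    ddl = _DDL + "".join(
        _VALUE_DDL.format(table=table, sqltype=sqltype)
        for table, sqltype in VALUE_TABLES.values()
    )
    for statement in ddl.split(";"):
        if statement.strip():
            conn.execute(statement)
    conn.execute(
        "INSERT INTO meta(key, value) VALUES('schema_version', ?)",
        (SCHEMA_VERSION,),
    )
    upload_ontology(repo, mm.metamodel_statements(), mode="incremental")
    return repo


# ---------------------------------------------------------------------------
# propagation


def _consistency_guard(repo: Repository, stmt: Statement):
    """Reject typing statements that contradict the live structural state."""
    if stmt.predicate != RDF_TYPE or isinstance(stmt.object, Literal):
        return
    s_id = repo.rid(stmt.subject)
    if stmt.object in _CLASS_TYPES:
        row = repo.one(
            "SELECT 1 FROM properties WHERE resource_id = ? AND deleted = 0",
            s_id,
        )
        if row:
            raise ContradictoryTypingError(stmt.subject, [stmt])
    elif stmt.object in _PROPERTY_TYPE_KIND:
        kind = _PROPERTY_TYPE_KIND[stmt.object]
        if repo.one(
            "SELECT 1 FROM classes WHERE resource_id = ? AND deleted = 0", s_id
        ):
            raise ContradictoryTypingError(stmt.subject, [stmt])
        row = repo.one(
            "SELECT kind FROM properties WHERE resource_id = ? AND deleted = 0",
            s_id,
        )
        if row and row[0] != kind:
            raise ContradictoryTypingError(stmt.subject, [stmt])


def _literal_host(repo: Repository, p_id: int, lit: Literal, effect):
    """Value table hosting a literal: the property's declared datatype range,
    else the string table (with a validation warning)."""
    rows = repo.q(
        "SELECT range_ref FROM ranges WHERE property_id = ? AND "
        "range_kind = 'datatype' AND deleted = 0 ORDER BY range_ref",
        p_id,
    ).fetchall()
    if not rows:
        if effect is not None:
            effect.warnings.append(
                f"property id {p_id} has no declared datatype range; "
                "value stored as string"
            )
        return "string", lit.lexical
    tag = rows[0][0]
    try:
        value = _coerce(lit.lexical, tag)
    except (ValueError, TypeError):
        if effect is not None:
            effect.warnings.append(
                f"literal {lit.lexical!r} does not fit declared range {tag}; "
                "stored as string"
            )
        return "string", lit.lexical
    return tag, value


def _coerce(lexical: str, tag: str):
    if tag == "string":
        return lexical
    if tag == "integer":
        return int(lexical)
    if tag == "float":
        return float(lexical)
    if tag == "boolean":
        low = lexical.strip().lower()
        if low in ("true", "1"):
            return 1
        if low in ("false", "0"):
            return 0
        raise ValueError(lexical)
    if tag == "date":
        import datetime

        return datetime.date.fromisoformat(lexical).isoformat()
    if tag == "datetime":
        import datetime

        return datetime.datetime.fromisoformat(lexical).isoformat()
    raise ValueError(tag)


def _value_row_for(repo, effect, s_id, p_id, obj):
    if isinstance(obj, Literal):
        tag, value = _literal_host(repo, p_id, obj, effect)
    else:
        tag, value = "resource", repo.rid(obj)
    table = VALUE_TABLES[tag][0]
    return table, (s_id, p_id, value)


def _is_live_property(repo, p_id):
    return (
        repo.one(
            "SELECT 1 FROM properties WHERE resource_id = ? AND deleted = 0",
            p_id,
        )
        is not None
    )


def _propagate_assert(repo: Repository, stmt: Statement, effect: PropagationEffect):
    s_id = repo.rid(stmt.subject, stmt.origin_ns)
    p = stmt.predicate
    obj = stmt.object
    o_is_lit = isinstance(obj, Literal)

    if p == RDF_TYPE and not o_is_lit:
        if obj in _CLASS_TYPES:
            repo._upsert(effect, "classes", ("resource_id",), (s_id,))
            repo.set_kind(s_id, "named_class")
            repo.mark_hierarchy_stale("class")
        elif obj in _PROPERTY_TYPE_KIND:
            kind = _PROPERTY_TYPE_KIND[obj]
            repo._upsert(
                effect, "properties", ("resource_id",), (s_id,), ("kind",), (kind,)
            )
            repo.set_kind(s_id, kind + "_property")
            repo.mark_hierarchy_stale("property")
            _rederive_values_of_property(repo, effect, s_id)
        elif obj == OWL_ONTOLOGY:
            ns = ontology_ns(stmt.subject)
            row = repo.one("SELECT iri, deleted FROM ontologies WHERE ns = ?", ns)
            if row is None:
                repo.q(
                    "INSERT INTO ontologies(ns, iri, deleted) VALUES(?, ?, 0)",
                    ns,
                    stmt.subject,
                )
                effect.count("inserted", "ontologies")
            elif row[0] != stmt.subject:
                raise NameCollisionError(
                    f"namespace {ns} already bound to ontology {row[0]}"
                )
            elif row[1]:
                repo.q("UPDATE ontologies SET deleted = 0 WHERE ns = ?", ns)
                effect.count("revived", "ontologies")
            repo.set_kind(s_id, "ontology")
        elif not is_builtin(obj):
            o_id = repo.rid(obj, stmt.origin_ns)
            repo._upsert(
                effect, "instances", ("instance_id", "class_id"), (s_id, o_id)
            )
            repo._upsert(effect, "classes", ("resource_id",), (o_id,))
            repo.mark_hierarchy_stale("class")
    elif p == RDFS_SUBCLASSOF and not o_is_lit:
        repo._upsert(effect, "classes", ("resource_id",), (s_id,))
        if not is_builtin(obj):
            o_id = repo.rid(obj, stmt.origin_ns)
            repo._upsert(effect, "classes", ("resource_id",), (o_id,))
            repo._upsert(
                effect,
                "subsumption",
                ("child_id", "parent_id", "kind"),
                (s_id, o_id, "class"),
            )
        repo.mark_hierarchy_stale("class")
    elif p == RDFS_SUBPROPERTYOF and not o_is_lit:
        if not is_builtin(obj):
            o_id = repo.rid(obj, stmt.origin_ns)
            repo._upsert(
                effect,
                "subsumption",
                ("child_id", "parent_id", "kind"),
                (s_id, o_id, "property"),
            )
        repo.mark_hierarchy_stale("property")
    elif p == RDFS_DOMAIN and not o_is_lit:
        o_id = repo.rid(obj, stmt.origin_ns)
        repo._upsert(effect, "domains", ("property_id", "class_id"), (s_id, o_id))
        if not is_builtin(obj):
            repo._upsert(effect, "classes", ("resource_id",), (o_id,))
    elif p == RDFS_RANGE and not o_is_lit:
        if obj in DATATYPE_TAG:
            key = (s_id, "datatype", DATATYPE_TAG[obj])
        else:
            key = (s_id, "resource", str(repo.rid(obj, stmt.origin_ns)))
            if not is_builtin(obj):
                repo._upsert(
                    effect, "classes", ("resource_id",), (repo.rid(obj),)
                )
        repo._upsert(
            effect, "ranges", ("property_id", "range_kind", "range_ref"), key
        )
        _rederive_values_of_property(repo, effect, s_id)
    elif p == OWL_IMPORTS and not o_is_lit:
        repo._upsert(
            effect, "imports", ("importer", "imported"), (stmt.subject, obj)
        )
    elif not is_builtin(p):
        p_id = repo.rid(p, stmt.origin_ns)
        if _is_live_property(repo, p_id):
            table, row = _value_row_for(repo, effect, s_id, p_id, obj)
            repo._upsert(
                effect, table, ("instance_id", "property_id", "value"), row
            )


def _statement_rows_of_property(repo, p_id):
    return repo.q(
        "SELECT subject_id, object_id, object_lexical, object_datatype, "
        "object_kind FROM statements WHERE predicate_id = ? AND deleted = 0",
        p_id,
    ).fetchall()


def _rederive_values_of_property(repo: Repository, effect, p_id: int):
    """Re-place all value rows of a property (range or typing changed)."""
    if is_builtin(repo.iri(p_id)):
        return
    live = _is_live_property(repo, p_id)
    target = {}
    if live:
        for s_id, o_id, lex, dtag, okind in _statement_rows_of_property(repo, p_id):
            if okind == "resource":
                tag, value = "resource", o_id
            else:
                tag, value = _literal_host(repo, p_id, Literal(lex, dtag), None)
            target.setdefault(VALUE_TABLES[tag][0], set()).add((s_id, value))
    for tag, (table, _) in VALUE_TABLES.items():
        want = target.get(table, set())
        have = {
            (r[0], r[1])
            for r in repo.q(
                f"SELECT instance_id, value FROM {table} "
                "WHERE property_id = ? AND deleted = 0",
                p_id,
            )
        }
        for s_id, value in want - have:
            repo._upsert(
                effect,
                table,
                ("instance_id", "property_id", "value"),
                (s_id, p_id, value),
            )
        for s_id, value in have - want:
            repo._flag(
                effect,
                table,
                ("instance_id", "property_id", "value"),
                (s_id, p_id, value),
            )


def assert_statement(repo: Repository, stmt: Statement) -> PropagationEffect:
    """Add one statement; structural tables update in the same transaction.

    Idempotent for duplicates.  Contradictory typing (a resource already
    live as a property being typed as a class, or vice versa) is rejected
    with the statements table unchanged.
    """
    effect = PropagationEffect()
    with repo.tx():
        _consistency_guard(repo, stmt)
        s_id = repo.rid(stmt.subject, stmt.origin_ns)
        p_id = repo.rid(stmt.predicate, stmt.origin_ns)
        kind, o_id, lex, dtag = repo._object_descriptor(stmt.object)
        row = repo.find_statement(stmt)
        if row is not None and not row[1]:
            return effect  # duplicate: zero-effect
        if row is None:
            repo.q(
                "INSERT INTO statements(subject_id, predicate_id, object_id, "
                "object_lexical, object_datatype, object_kind, ontology_ns, "
                "deleted) VALUES(?, ?, ?, ?, ?, ?, ?, 0)",
                s_id,
                p_id,
                o_id,
                lex,
                dtag,
                kind,
                stmt.origin_ns,
            )
            effect.count("inserted", "statements")
        else:
            repo.q("UPDATE statements SET deleted = 0 WHERE id = ?", row[0])
            effect.count("revived", "statements")
        for rid in {s_id, p_id} | ({o_id} if o_id else set()):
            repo._set_resource_deleted(rid, False)
        _propagate_assert(repo, stmt, effect)
    return effect


# -- retract -----------------------------------------------------------------


def _class_supported(repo, c_id):
    """Does any live statement still derive a classes row for this resource?

    Mirrors exactly the class-derivation rules of :func:`rebuild_structural`.
    """
    iri = repo.iri(c_id)
    # typed as a class
    if repo.one(
        "SELECT 1 FROM statements s JOIN resources p ON p.id = s.predicate_id "
        "JOIN resources o ON o.id = s.object_id "
        "WHERE s.deleted = 0 AND s.subject_id = ? AND p.iri = ? "
        "AND o.iri IN (?, ?) LIMIT 1",
        c_id,
        RDF_TYPE,
        OWL_CLASS,
        RDFS_CLASS,
    ):
        return True
    # subject of subClassOf (with a resource object)
    if repo.one(
        "SELECT 1 FROM statements s JOIN resources p ON p.id = s.predicate_id "
        "WHERE s.deleted = 0 AND s.subject_id = ? AND p.iri = ? "
        "AND s.object_kind = 'resource' LIMIT 1",
        c_id,
        RDFS_SUBCLASSOF,
    ):
        return True
    if is_builtin(iri):
        return False
    # object of subClassOf / rdf:type / domain / range (non-builtin only)
    return (
        repo.one(
            "SELECT 1 FROM statements s JOIN resources p ON p.id = s.predicate_id "
            "WHERE s.deleted = 0 AND s.object_id = ? AND p.iri IN (?, ?, ?, ?) "
            "LIMIT 1",
            c_id,
            RDFS_SUBCLASSOF,
            RDF_TYPE,
            RDFS_DOMAIN,
            RDFS_RANGE,
        )
        is not None
    )


def _triple_live(repo, stmt: Statement) -> bool:
    """Is the (s, p, o) triple still asserted live in *any* namespace?"""
    s_row = repo.one("SELECT id FROM resources WHERE iri = ?", stmt.subject)
    p_row = repo.one("SELECT id FROM resources WHERE iri = ?", stmt.predicate)
    if s_row is None or p_row is None:
        return False
    if isinstance(stmt.object, Literal):
        row = repo.one(
            "SELECT 1 FROM statements WHERE deleted = 0 AND subject_id = ? "
            "AND predicate_id = ? AND object_kind = 'literal' AND "
            "object_lexical = ? AND object_datatype = ? LIMIT 1",
            s_row[0],
            p_row[0],
            stmt.object.lexical,
            stmt.object.datatype,
        )
    else:
        o_row = repo.one("SELECT id FROM resources WHERE iri = ?", stmt.object)
        if o_row is None:
            return False
        row = repo.one(
            "SELECT 1 FROM statements WHERE deleted = 0 AND subject_id = ? "
            "AND predicate_id = ? AND object_kind = 'resource' AND "
            "object_id = ? LIMIT 1",
            s_row[0],
            p_row[0],
            o_row[0],
        )
    return row is not None


def _sync_value_pair(repo, effect, s_id, p_id):
    """Re-derive the value rows of one (instance, property) pair.

    Needed on retract because distinct lexical forms may coerce to the same
    stored value (e.g. "1" and "01" as integers), so a value row can be
    supported by more than one live statement.
    """
    target = {}
    if _is_live_property(repo, p_id):
        for o_id, lex, dtag, okind in repo.q(
            "SELECT object_id, object_lexical, object_datatype, object_kind "
            "FROM statements WHERE deleted = 0 AND subject_id = ? AND "
            "predicate_id = ?",
            s_id,
            p_id,
        ):
            if okind == "resource":
                tag, value = "resource", o_id
            else:
                tag, value = _literal_host(repo, p_id, Literal(lex, dtag), None)
            target.setdefault(VALUE_TABLES[tag][0], set()).add(value)
    for tag, (table, _) in VALUE_TABLES.items():
        want = target.get(table, set())
        have = {
            r[0]
            for r in repo.q(
                f"SELECT value FROM {table} WHERE instance_id = ? AND "
                "property_id = ? AND deleted = 0",
                s_id,
                p_id,
            )
        }
        for value in want - have:
            repo._upsert(
                effect,
                table,
                ("instance_id", "property_id", "value"),
                (s_id, p_id, value),
            )
        for value in have - want:
            repo._flag(
                effect,
                table,
                ("instance_id", "property_id", "value"),
                (s_id, p_id, value),
            )


def _retract_guard(repo: Repository, stmt: Statement):
    if stmt.predicate != RDF_TYPE or isinstance(stmt.object, Literal):
        return
    s_id = repo.rid(stmt.subject)
    if stmt.object in _CLASS_TYPES:
        row = repo.one(
            "SELECT COUNT(*) FROM instances WHERE class_id = ? AND deleted = 0",
            s_id,
        )
        if row[0]:
            raise GuardViolationError(
                f"cannot retract class typing of {stmt.subject}: "
                f"{row[0]} live instance(s) exist"
            )
    elif stmt.object in _PROPERTY_TYPE_KIND:
        for table, _ in VALUE_TABLES.values():
            row = repo.one(
                f"SELECT COUNT(*) FROM {table} WHERE property_id = ? AND deleted = 0",
                s_id,
            )
            if row[0]:
                raise GuardViolationError(
                    f"cannot retract property typing of {stmt.subject}: "
                    f"live values exist"
                )


def _propagate_retract(repo: Repository, stmt: Statement, effect):
    if _triple_live(repo, stmt):
        # the same triple is still asserted in another namespace: every
        # structural row it derives remains supported
        return
    s_id = repo.rid(stmt.subject)
    p = stmt.predicate
    obj = stmt.object
    o_is_lit = isinstance(obj, Literal)
    o_id = None if o_is_lit else repo.rid(obj)

    if p == RDF_TYPE and not o_is_lit:
        if obj in _CLASS_TYPES:
            if not _class_supported(repo, s_id):
                repo._flag(effect, "classes", ("resource_id",), (s_id,))
                repo.mark_hierarchy_stale("class")
        elif obj in _PROPERTY_TYPE_KIND:
            repo._flag(effect, "properties", ("resource_id",), (s_id,))
            repo.mark_hierarchy_stale("property")
            _rederive_values_of_property(repo, effect, s_id)
        elif obj == OWL_ONTOLOGY:
            ns = ontology_ns(stmt.subject)
            cur = repo.q(
                "UPDATE ontologies SET deleted = 1 WHERE ns = ? AND deleted = 0",
                ns,
            )
            effect.count("flagged", "ontologies", cur.rowcount)
        elif not is_builtin(obj):
            repo._flag(
                effect, "instances", ("instance_id", "class_id"), (s_id, o_id)
            )
            if not _class_supported(repo, o_id):
                repo._flag(effect, "classes", ("resource_id",), (o_id,))
                repo.mark_hierarchy_stale("class")
    elif p == RDFS_SUBCLASSOF and not o_is_lit:
        if not is_builtin(obj):
            repo._flag(
                effect,
                "subsumption",
                ("child_id", "parent_id", "kind"),
                (s_id, o_id, "class"),
            )
        for rid in (s_id,) + (() if is_builtin(obj) else (o_id,)):
            if not _class_supported(repo, rid):
                repo._flag(effect, "classes", ("resource_id",), (rid,))
        repo.mark_hierarchy_stale("class")
    elif p == RDFS_SUBPROPERTYOF and not o_is_lit:
        if not is_builtin(obj):
            repo._flag(
                effect,
                "subsumption",
                ("child_id", "parent_id", "kind"),
                (s_id, o_id, "property"),
            )
        repo.mark_hierarchy_stale("property")
    elif p == RDFS_DOMAIN and not o_is_lit:
        repo._flag(effect, "domains", ("property_id", "class_id"), (s_id, o_id))
        if not is_builtin(obj) and not _class_supported(repo, o_id):
            repo._flag(effect, "classes", ("resource_id",), (o_id,))
    elif p == RDFS_RANGE and not o_is_lit:
        if obj in DATATYPE_TAG:
            key = (s_id, "datatype", DATATYPE_TAG[obj])
        else:
            key = (s_id, "resource", str(o_id))
            if not is_builtin(obj) and not _class_supported(repo, o_id):
                repo._flag(effect, "classes", ("resource_id",), (o_id,))
        repo._flag(effect, "ranges", ("property_id", "range_kind", "range_ref"), key)
        _rederive_values_of_property(repo, effect, s_id)
    elif p == OWL_IMPORTS and not o_is_lit:
        repo._flag(effect, "imports", ("importer", "imported"), (stmt.subject, obj))
    elif not is_builtin(p):
        p_id = repo.rid(p)
        _sync_value_pair(repo, effect, s_id, p_id)


def retract_statement(repo: Repository, stmt: Statement) -> PropagationEffect:
    """Soft-delete one statement; dependent structural rows are flagged.

    Guarded: class typings with live instances and property typings with
    live values are refused (the repository enforces the same consistency
    protections an ontology editor would).
    """
    effect = PropagationEffect()
    with repo.tx():
        row = repo.find_statement(stmt)
        if row is None or row[1]:
            raise UnknownResourceError(f"statement not live: {stmt}")
        _retract_guard(repo, stmt)
        repo.q("UPDATE statements SET deleted = 1 WHERE id = ?", row[0])
        effect.count("flagged", "statements")
        _propagate_retract(repo, stmt, effect)
        ids = {repo.rid(stmt.subject), repo.rid(stmt.predicate)}
        if not isinstance(stmt.object, Literal):
            ids.add(repo.rid(stmt.object))
        for rid in ids:
            if not repo._mentioned(rid):
                repo._set_resource_deleted(rid, True)
    return effect


# ---------------------------------------------------------------------------
# rebuild oracle and bulk application


def structural_state(repo: Repository) -> dict:
    """Current live structural rows, as comparable frozensets."""
    out = {}
    out["resources"] = frozenset(
        r for (r,) in repo.q("SELECT id FROM resources WHERE deleted = 0")
    )
    out["classes"] = frozenset(
        r for (r,) in repo.q("SELECT resource_id FROM classes WHERE deleted = 0")
    )
    out["properties"] = frozenset(
        (r, k)
        for r, k in repo.q(
            "SELECT resource_id, kind FROM properties WHERE deleted = 0"
        )
    )
    out["domains"] = frozenset(
        tuple(r)
        for r in repo.q(
            "SELECT property_id, class_id FROM domains WHERE deleted = 0"
        )
    )
    out["ranges"] = frozenset(
        tuple(r)
        for r in repo.q(
            "SELECT property_id, range_kind, range_ref FROM ranges "
            "WHERE deleted = 0"
        )
    )
    out["subsumption"] = frozenset(
        tuple(r)
        for r in repo.q(
            "SELECT child_id, parent_id, kind FROM subsumption WHERE deleted = 0"
        )
    )
    out["instances"] = frozenset(
        tuple(r)
        for r in repo.q(
            "SELECT instance_id, class_id FROM instances WHERE deleted = 0"
        )
    )
    out["imports"] = frozenset(
        tuple(r)
        for r in repo.q("SELECT importer, imported FROM imports WHERE deleted = 0")
    )
    out["ontologies"] = frozenset(
        tuple(r)
        for r in repo.q("SELECT ns, iri FROM ontologies WHERE deleted = 0")
    )
    values = set()
    for tag, (table, _) in VALUE_TABLES.items():
        for i, p, v in repo.q(
            f"SELECT instance_id, property_id, value FROM {table} "
            "WHERE deleted = 0"
        ):
            values.add((tag, i, p, v))
    out["values"] = frozenset(values)
    return out


def rebuild_structural(repo: Repository) -> dict:
    """From-scratch derivation of the structural state from live statements.

    This is a pure computation over the statements table (the interface
    table); it shares no state with the incremental propagation path and
    serves as its oracle, as well as the bulk-load application step.
    """
    rows = repo.q(
        "SELECT s.subject_id, s.predicate_id, s.object_id, s.object_lexical, "
        "s.object_datatype, s.object_kind, s.ontology_ns, rs.iri, rp.iri, ro.iri "
        "FROM statements s JOIN resources rs ON rs.id = s.subject_id "
        "JOIN resources rp ON rp.id = s.predicate_id "
        "LEFT JOIN resources ro ON ro.id = s.object_id WHERE s.deleted = 0"
    ).fetchall()

    classes = set()
    properties = {}
    domains = set()
    ranges = set()
    subsumption = set()
    instances = set()
    imports = set()
    ontologies = set()
    mentioned = set()
    pending_values = []

    for s_id, p_id, o_id, lex, dtag, okind, ns, s_iri, p_iri, o_iri in rows:
        mentioned.add(s_id)
        mentioned.add(p_id)
        if o_id is not None:
            mentioned.add(o_id)
        if p_iri == RDF_TYPE and okind == "resource":
            if o_iri in _CLASS_TYPES:
                classes.add(s_id)
            elif o_iri in _PROPERTY_TYPE_KIND:
                kind = _PROPERTY_TYPE_KIND[o_iri]
                if s_id not in properties or kind < properties[s_id]:
                    properties[s_id] = kind
            elif o_iri == OWL_ONTOLOGY:
                ontologies.add((ontology_ns(s_iri), s_iri))
            elif not is_builtin(o_iri):
                instances.add((s_id, o_id))
                classes.add(o_id)
        elif p_iri == RDFS_SUBCLASSOF and okind == "resource":
            classes.add(s_id)
            if not is_builtin(o_iri):
                classes.add(o_id)
                subsumption.add((s_id, o_id, "class"))
        elif p_iri == RDFS_SUBPROPERTYOF and okind == "resource":
            if not is_builtin(o_iri):
                subsumption.add((s_id, o_id, "property"))
        elif p_iri == RDFS_DOMAIN and okind == "resource":
            domains.add((s_id, o_id))
            if not is_builtin(o_iri):
                classes.add(o_id)
        elif p_iri == RDFS_RANGE and okind == "resource":
            if o_iri in DATATYPE_TAG:
                ranges.add((s_id, "datatype", DATATYPE_TAG[o_iri]))
            else:
                ranges.add((s_id, "resource", str(o_id)))
                if not is_builtin(o_iri):
                    classes.add(o_id)
        elif p_iri == OWL_IMPORTS and okind == "resource":
            imports.add((s_iri, o_iri))
        elif not is_builtin(p_iri):
            pending_values.append((s_id, p_id, o_id, lex, dtag, okind))

    dt_ranges = {}
    for p_id, kind, ref in ranges:
        if kind == "datatype":
            dt_ranges.setdefault(p_id, []).append(ref)
    values = set()
    for s_id, p_id, o_id, lex, dtag, okind in pending_values:
        if p_id not in properties:
            continue
        if okind == "resource":
            values.add(("resource", s_id, p_id, o_id))
        else:
            tags = sorted(dt_ranges.get(p_id, []))
            if not tags:
                values.add(("string", s_id, p_id, lex))
            else:
                try:
                    values.add((tags[0], s_id, p_id, _coerce(lex, tags[0])))
                except (ValueError, TypeError):
                    values.add(("string", s_id, p_id, lex))

    return {
        "resources": frozenset(mentioned),
        "classes": frozenset(classes),
        "properties": frozenset(properties.items()),
        "domains": frozenset(domains),
        "ranges": frozenset(ranges),
        "subsumption": frozenset(subsumption),
        "instances": frozenset(instances),
        "imports": frozenset(imports),
        "ontologies": frozenset(ontologies),
        "values": frozenset(values),
    }


def _sync_table(repo, table, key_cols, extra_cols, want_rows):
    """Batch-sync one table to a target row set (insert/revive/flag)."""
    n_key = len(key_cols)
    existing = {}
    for row in repo.q(
        f"SELECT {', '.join(key_cols)}, deleted FROM {table}"
    ):
        existing[tuple(row[:n_key])] = row[n_key]
    want = {}
    for row in want_rows:
        row_t = row if isinstance(row, tuple) else (row,)
        want[tuple(row_t[:n_key])] = tuple(row_t[n_key:])
    all_cols = list(key_cols) + list(extra_cols)
    inserts = [
        key + want[key] for key in want if key not in existing
    ]
    if inserts:
        placeholders = ", ".join("?" for _ in all_cols)
        repo.conn.executemany(
            f"INSERT INTO {table}({', '.join(all_cols)}, deleted) "
            f"VALUES({placeholders}, 0)",
            inserts,
        )
    where = " AND ".join(f"{c} = ?" for c in key_cols)
    revives = [
        list(want[key]) + list(key)
        for key in want
        if key in existing and existing[key]
    ]
    if revives:
        sets = ", ".join(
            ["deleted = 0"] + [f"{c} = ?" for c in extra_cols]
        )
        repo.conn.executemany(
            f"UPDATE {table} SET {sets} WHERE {where}", revives
        )
    flags = [
        list(key) for key, deleted in existing.items()
        if not deleted and key not in want
    ]
    if flags:
        repo.conn.executemany(
            f"UPDATE {table} SET deleted = 1 WHERE {where}", flags
        )
    return len(inserts), len(revives), len(flags)


def apply_structural_state(repo: Repository, target: dict):
    """Sync the structural tables to a derived target state in batch.

    This is the bulk-load application step: one set-difference pass per
    table instead of per-statement propagation.
    """
    effect = PropagationEffect()
    with repo.tx():
        live = {
            r for (r,) in repo.q("SELECT id FROM resources WHERE deleted = 0")
        }
        for rid in target["resources"] - live:
            repo._set_resource_deleted(rid, False)
        for rid in live - target["resources"]:
            repo._set_resource_deleted(rid, True)
        plans = [
            ("classes", ("resource_id",), ()),
            ("properties", ("resource_id",), ("kind",)),
            ("domains", ("property_id", "class_id"), ()),
            ("ranges", ("property_id", "range_kind", "range_ref"), ()),
            ("subsumption", ("child_id", "parent_id", "kind"), ()),
            ("instances", ("instance_id", "class_id"), ()),
            ("imports", ("importer", "imported"), ()),
            ("ontologies", ("ns", "iri"), ()),
        ]
        for table, key_cols, extra_cols in plans:
            ins, rev, flg = _sync_table(
                repo, table, key_cols, extra_cols, target[table]
            )
            effect.count("inserted", table, ins)
            effect.count("revived", table, rev)
            effect.count("flagged", table, flg)
        for tag, (table, _) in VALUE_TABLES.items():
            rows = {(i, p, v) for t, i, p, v in target["values"] if t == tag}
            ins, rev, flg = _sync_table(
                repo, table, ("instance_id", "property_id", "value"), (), rows
            )
            effect.count("inserted", table, ins)
            effect.count("revived", table, rev)
            effect.count("flagged", table, flg)
    repo.mark_hierarchy_stale("class")
    repo.mark_hierarchy_stale("property")
    return effect


# ---------------------------------------------------------------------------
# ontology-level operations


def _skolemize_blank(label: str, ns: str) -> str:
    tag = hashlib.md5(ns.encode()).hexdigest()[:8]
    return f"_:{tag}.{label[2:]}"


def _prepare_statements(stmts: StatementSet):
    """Canonically ordered statements with namespace-scoped blank labels."""
    ns = stmts.origin_ns
    out = []
    for s in sorted(stmts.statements, key=Statement.sort_key):
        subject = _skolemize_blank(s.subject, ns) if is_blank(s.subject) else s.subject
        obj = s.object
        if isinstance(obj, str) and is_blank(obj):
            obj = _skolemize_blank(obj, ns)
        out.append(Statement(subject, s.predicate, obj, ns))
    return ns, out


def _register_ontology(repo, ns, stmts):
    row = repo.one("SELECT iri FROM ontologies WHERE ns = ?", ns)
    if row is not None and stmts.ontology_iri and row[0] != stmts.ontology_iri:
        raise NameCollisionError(
            f"namespace {ns} already bound to ontology {row[0]}, "
            f"refusing {stmts.ontology_iri}"
        )


def upload_ontology(
    repo: Repository,
    stmts: StatementSet,
    mode: str = "replace",
    with_imports: bool = False,
    resolver=None,
) -> dict:
    """Load one ontology through the statement-by-statement editor path.

    ``replace`` soft-deletes the namespace's statements that are absent
    from the new set before asserting the new ones; ``incremental`` only
    applies the additions.  With ``with_imports`` the resolved import
    closure is loaded first (imported ontologies before importers).  The
    hierarchy index is rebuilt once at the end of the bulk load.
    """
    if mode not in ("replace", "incremental"):
        raise ValueError(f"unknown upload mode {mode!r}")
    sets = [stmts]
    if with_imports:
        if resolver is None:
            raise ValueError("with_imports requires a resolver")
        loaded = {
            r[0] for r in repo.q("SELECT iri FROM ontologies WHERE deleted = 0")
        }

        def _resolve(iri):
            return resolver(iri)

        sets = [
            s
            for s in import_closure(stmts, _resolve)
            if s.ontology_iri == stmts.ontology_iri or s.ontology_iri not in loaded
        ]
    summary = {"asserted": 0, "retracted": 0, "ontologies": []}
    with repo.tx():
        for sset in sets:
            ns, prepared = _prepare_statements(sset)
            _register_ontology(repo, ns, sset)
            known = {r[0] for r in repo.q("SELECT ns FROM ontologies")}
            if mode == "replace" and ns in known:
                new_keys = {
                    (s.subject, s.predicate, repr(s.object)) for s in prepared
                }
                for old in download_ontology(repo, ns).statements:
                    if (old.subject, old.predicate, repr(old.object)) not in new_keys:
                        retract_statement(repo, old)
                        summary["retracted"] += 1
            for s in prepared:
                effect = assert_statement(repo, s)
                if not effect.is_noop:
                    summary["asserted"] += 1
            summary["ontologies"].append(sset.ontology_iri)
    repo.rebuild_hierarchy()
    return summary


def download_ontology(
    repo: Repository, ns: str, with_imports: bool = False
) -> StatementSet:
    """Live statements of one namespace (optionally plus its import closure)."""
    known = {r[0] for r in repo.q("SELECT ns FROM ontologies")}
    if ns not in known:
        raise UnknownResourceError(
            f"namespace {ns} not loaded; loaded namespaces: {sorted(known)}"
        )
    namespaces = {ns}
    if with_imports:
        frontier = [ns]
        iri_to_ns = {
            iri: n for n, iri in repo.q("SELECT ns, iri FROM ontologies")
        }
        while frontier:
            current = frontier.pop()
            row = repo.one("SELECT iri FROM ontologies WHERE ns = ?", current)
            if row is None:
                continue
            for (imported,) in repo.q(
                "SELECT imported FROM imports WHERE importer = ? AND deleted = 0",
                row[0],
            ):
                target_ns = iri_to_ns.get(imported, ontology_ns(imported))
                if target_ns not in namespaces:
                    namespaces.add(target_ns)
                    frontier.append(target_ns)
    statements = []
    for n in sorted(namespaces):
        rows = repo.q(
            "SELECT rs.iri, rp.iri, ro.iri, s.object_lexical, s.object_datatype, "
            "s.object_kind FROM statements s "
            "JOIN resources rs ON rs.id = s.subject_id "
            "JOIN resources rp ON rp.id = s.predicate_id "
            "LEFT JOIN resources ro ON ro.id = s.object_id "
            "WHERE s.deleted = 0 AND s.ontology_ns = ?",
            n,
        )
        for s_iri, p_iri, o_iri, lex, dtag, okind in rows:
            obj = Literal(lex, dtag) if okind == "literal" else o_iri
            statements.append(Statement(s_iri, p_iri, obj, n))
    row = repo.one("SELECT iri FROM ontologies WHERE ns = ? AND deleted = 0", ns)
    sset = StatementSet.from_statements(statements, origin_ns=ns)
    if row is not None:
        sset.ontology_iri = row[0]
    return sset


# ---------------------------------------------------------------------------
# stored-procedure-style query API


def _live_resource(repo, rid):
    row = repo.one("SELECT deleted FROM resources WHERE id = ?", rid)
    if row is None or row[0]:
        raise UnknownResourceError(f"resource id {rid} unknown or deleted")


def subclasses_of(repo: Repository, class_id: int, transitive: bool = False):
    """Direct or transitive (via nested-set intervals) subclasses."""
    _live_resource(repo, class_id)
    if not transitive:
        return {
            c
            for (c,) in repo.q(
                "SELECT child_id FROM subsumption WHERE parent_id = ? "
                "AND kind = 'class' AND deleted = 0",
                class_id,
            )
        }
    return _interval_descendants(repo, class_id, "class")


def subproperties_of(repo: Repository, prop_id: int, transitive: bool = False):
    _live_resource(repo, prop_id)
    if not transitive:
        return {
            c
            for (c,) in repo.q(
                "SELECT child_id FROM subsumption WHERE parent_id = ? "
                "AND kind = 'property' AND deleted = 0",
                prop_id,
            )
        }
    return _interval_descendants(repo, prop_id, "property")


def _interval_descendants(repo, rid, kind):
    repo._ensure_hierarchy(kind)
    out = set()
    for lft, rgt in repo.q(
        "SELECT lft, rgt FROM hierarchy_index WHERE resource_id = ? AND kind = ?",
        rid,
        kind,
    ):
        for (r,) in repo.q(
            "SELECT DISTINCT resource_id FROM hierarchy_index "
            "WHERE kind = ? AND lft > ? AND lft < ?",
            kind,
            lft,
            rgt,
        ):
            out.add(r)
    out.discard(rid)
    return out


def superclasses_of(repo: Repository, class_id: int, transitive: bool = False):
    _live_resource(repo, class_id)
    if not transitive:
        return {
            p
            for (p,) in repo.q(
                "SELECT parent_id FROM subsumption WHERE child_id = ? "
                "AND kind = 'class' AND deleted = 0",
                class_id,
            )
        }
    repo._ensure_hierarchy("class")
    out = set()
    for lft, rgt in repo.q(
        "SELECT lft, rgt FROM hierarchy_index WHERE resource_id = ? "
        "AND kind = 'class'",
        class_id,
    ):
        for (r,) in repo.q(
            "SELECT DISTINCT resource_id FROM hierarchy_index "
            "WHERE kind = 'class' AND lft < ? AND rgt > ?",
            lft,
            rgt,
        ):
            out.add(r)
    out.discard(class_id)
    return out


def instances_of(repo: Repository, class_id: int, transitive: bool = False):
    """Instances of a class; transitively, of all its descendants too."""
    _live_resource(repo, class_id)
    targets = {class_id}
    if transitive:
        targets |= subclasses_of(repo, class_id, transitive=True)
    out = set()
    for cid in targets:
        for (i,) in repo.q(
            "SELECT instance_id FROM instances WHERE class_id = ? AND deleted = 0",
            cid,
        ):
            out.add(i)
    return out


def properties_of(repo: Repository, class_id: int, inherited: bool = False):
    """Properties whose domain is the class (optionally plus ancestors')."""
    _live_resource(repo, class_id)
    targets = {class_id}
    if inherited:
        targets |= superclasses_of(repo, class_id, transitive=True)
    out = set()
    for cid in targets:
        for (p,) in repo.q(
            "SELECT property_id FROM domains WHERE class_id = ? AND deleted = 0",
            cid,
        ):
            out.add(p)
    return out


def domain_of(repo: Repository, property_id: int):
    _live_resource(repo, property_id)
    return {
        c
        for (c,) in repo.q(
            "SELECT class_id FROM domains WHERE property_id = ? AND deleted = 0",
            property_id,
        )
    }


def range_of(repo: Repository, property_id: int):
    """Declared ranges: set of ('datatype', tag) or ('resource', class id)."""
    _live_resource(repo, property_id)
    out = set()
    for kind, ref in repo.q(
        "SELECT range_kind, range_ref FROM ranges WHERE property_id = ? "
        "AND deleted = 0",
        property_id,
    ):
        out.add((kind, int(ref) if kind == "resource" else ref))
    return out


def values_of(repo: Repository, instance_id: int, property_id: int | None = None):
    """Typed values of an instance, as {property_id: [(tag, value), ...]}."""
    _live_resource(repo, instance_id)
    out = {}
    for tag, (table, _) in VALUE_TABLES.items():
        sql = (
            f"SELECT property_id, value FROM {table} "
            "WHERE instance_id = ? AND deleted = 0"
        )
        params = [instance_id]
        if property_id is not None:
            sql += " AND property_id = ?"
            params.append(property_id)
        for p, v in repo.q(sql, *params):
            out.setdefault(p, []).append((tag, v))
    return out


def physical_row_count(repo: Repository) -> int:
    """Total physical rows across all data tables (soft-delete conservation).

    The hierarchy index is excluded: it is derived data, recalculated as a
    whole by batch rebuilds, not part of the soft-deleted record of facts.
    """
    total = 0
    for table in REQUIRED_TABLES:
        if table in ("meta", "counters", "hierarchy_index"):
            continue
        total += repo.one(f"SELECT COUNT(*) FROM {table}")[0]
    return total
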