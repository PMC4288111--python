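"""Form-model compilation and constraint-enforcing instance CRUD.

A validated application ontology is compiled into a renderable form model:
a navigation menu (one entry per menu-typed object property), one field
grid per data structure, and the description columns used in instance
lists.  The model is a plain JSON-serializable document — this package
deliberately ships no web server; any front end can render the bundle.

Instance operations enforce the facet constraints declared in the
ontology: mandatory fields, unique id fields, option membership for
constrained fields, range typing, edit locking, and the dependent cascade
on delete.  All mutations are soft: nothing is ever physically removed,
and any rejected mutation leaves the repository untouched.  Creating an
instance of a reportable data structure emits exactly one notification
(recorded in the repository and passed to an optional callback hook —
delivery is out of scope).
"""

from __future__ import annotations

import datetime
import hashlib
from dataclasses import dataclass

from pydantic import BaseModel, Field

from . import store
from .exceptions import (
    RejectionError,
    UnknownResourceError,
    ValidationFailedError,
)
from .metamodel import (
    DATA_STRUCTURE,
    GraphView,
    WEB_DIRECTLY_DEPENDENT,
    field_specs,
    metamodel_statements,
    validate_application,
)
from .namespaces import RDF_TYPE, RDFS_DOMAIN, RDFS_RANGE, local_name
from .owl_core import Literal, Statement, StatementSet


# ---------------------------------------------------------------------------
# form model documents

FORM_MODEL_VERSION = "1"


class OptionModel(BaseModel):
    iri: str
    label: str
    rank: int
    code: str | None = None


class FieldModel(BaseModel):
    property: str
    widget: str
    row: int
    col: int
    mandatory: bool = False
    is_id: bool = False
    description: bool = False
    edition_disabled: bool = False
    directly_dependent: bool = False
    value_type: str = "string"
    target: str | None = None
    options: list[OptionModel] = Field(default_factory=list)
    label: str = ""


class MenuEntry(BaseModel):
    label: str
    property: str
    target: str


class FormModel(BaseModel):
    """The compiled, renderable description of an application."""

    version: str = FORM_MODEL_VERSION
    application: str
    menu: list[MenuEntry] = Field(default_factory=list)
    forms: dict[str, list[FieldModel]] = Field(default_factory=dict)
    description_columns: dict[str, list[str]] = Field(default_factory=dict)


def compile_forms(app: StatementSet) -> FormModel:
    """Compile a validated application ontology into a form model.

    Deterministic: compiling the same statement set twice yields identical
    models (and byte-identical JSON renderings).  Invalid applications are
    refused with a pointer to the validation report.
    """
    report = validate_application(app)
    if not report.is_valid:
        raise ValidationFailedError(report)
    g = GraphView(app, metamodel_statements())
    apps = g.applications()
    menu = []
    for prop in g.menu_properties():
        target = g.object(prop, RDFS_RANGE)
        menu.append(
            MenuEntry(
                label=local_name(target) if target else local_name(prop),
                property=prop,
                target=target or "",
            )
        )
    forms = {}
    description_columns = {}
    for ds in g.data_structures():
        fields = []
        for spec in field_specs(app, ds, graph=g):
            if spec.widget == "SubForm":
                continue  # accepted by the validator (warning), not rendered
            fields.append(
                FieldModel(
                    property=spec.property_iri,
                    widget=spec.widget,
                    row=spec.facets.web_row,
                    col=spec.facets.web_column,
                    mandatory=spec.facets.is_mandatory,
                    is_id=spec.facets.is_id,
                    description=spec.facets.is_description,
                    edition_disabled=spec.facets.edition_disabled,
                    directly_dependent=spec.facets.directly_dependent,
                    value_type=spec.value_type,
                    target=spec.target,
                    options=[OptionModel(**vars(o)) for o in spec.options],
                    label=spec.label,
                )
            )
        forms[ds] = fields
        description_columns[ds] = [
            f.property for f in fields if f.description
        ]
    return FormModel(
        application=apps[0] if apps else "",
        menu=menu,
        forms=forms,
        description_columns=description_columns,
    )


def render_form_model(model: FormModel) -> str:
    """Schema-stable JSON rendering; identical models render byte-identically."""
    return model.model_dump_json(indent=2)


def parse_form_model(document: str) -> FormModel:
    return FormModel.model_validate_json(document)


def form_model_json_schema() -> dict:
    """The JSON schema of the form-model document (shipped with the package)."""
    return FormModel.model_json_schema()


def render_html(model: FormModel) -> str:
    """Optional static HTML rendering of a form model, for human inspection."""
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>{local_name(model.application)}</title></head><body>",
        f"<h1>{local_name(model.application)}</h1><nav><ul>",
    ]
    for entry in model.menu:
        parts.append(f"<li><a href='#{local_name(entry.target)}'>{entry.label}</a></li>")
    parts.append("</ul></nav>")
    for ds, fields in model.forms.items():
        parts.append(f"<section id='{local_name(ds)}'><h2>{local_name(ds)}</h2><table>")
        for f in sorted(fields, key=lambda f: (f.row, f.col)):
            flag = " *" if f.mandatory else ""
            parts.append(
                f"<tr><td>{f.label}{flag}</td><td>[{f.widget}]</td></tr>"
            )
        parts.append("</table></section>")
    parts.append("</body></html>")
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# instance CRUD


@dataclass(frozen=True)
class Notification:
    """Emitted once per creation of a reportable data-structure instance."""

    data_structure: str
    instance_id: int
    timestamp: str
    recipients: tuple = ()


def _password_digest(instance_iri, prop_iri, value):
    salt = hashlib.sha256(f"{instance_iri}|{prop_iri}".encode()).hexdigest()[:16]
    return "sha256$" + salt + "$" + hashlib.sha256(
        (salt + value).encode()
    ).hexdigest()


def _to_literal(value, tag) -> Literal:
    if isinstance(value, Literal):
        return value
    if tag == "boolean":
        lex = "true" if value in (True, 1, "true", "1") else "false"
    elif tag in ("date", "datetime"):
        lex = value.isoformat() if hasattr(value, "isoformat") else str(value)
    else:
        lex = str(value)
    return Literal(lex, tag if tag in ("string", "integer", "float", "boolean", "date", "datetime") else "string")


def _check_type(value, tag):
    try:
        if tag == "integer":
            int(str(value))
        elif tag == "float":
            float(str(value))
        elif tag == "boolean":
            if str(value).strip().lower() not in ("true", "false", "0", "1"):
                raise ValueError(value)
        elif tag == "date":
            if not hasattr(value, "isoformat"):
                datetime.date.fromisoformat(str(value))
        elif tag == "datetime":
            if not hasattr(value, "isoformat"):
                datetime.datetime.fromisoformat(str(value))
    except (ValueError, TypeError) as exc:
        raise RejectionError(
            "TYPE_MISMATCH", f"value {value!r} does not fit range {tag}"
        ) from exc


class Registry:
    """CRUD engine over one application loaded in a repository.

    Instance data lives in a data namespace derived from the application's
    model namespace, so replacing the model ontology never touches captured
    data.  ``notify`` is an optional callable receiving a
    :class:`Notification` after each reportable creation.
    """

    def __init__(self, repo: store.Repository, app_ns: str, notify=None):
        self.repo = repo
        self.app_ns = app_ns
        self.app = store.download_ontology(repo, app_ns)
        report = validate_application(self.app)
        if not report.is_valid:
            raise ValidationFailedError(report)
        self.graph = GraphView(self.app, metamodel_statements())
        base = app_ns[:-1] if app_ns.endswith(("#", "/")) else app_ns
        self.data_ns = base + "/data#"
        self.notify = notify
        self._specs_cache = {}

    # -- helpers -----------------------------------------------------------

    def specs(self, ds_iri):
        if ds_iri not in self._specs_cache:
            self._specs_cache[ds_iri] = [
                s
                for s in field_specs(self.app, ds_iri, graph=self.graph)
                if s.widget != "SubForm"
            ]
        return self._specs_cache[ds_iri]

    def _check_data_structure(self, ds_iri):
        if ds_iri not in self.graph.instances(DATA_STRUCTURE):
            raise UnknownResourceError(
                f"{ds_iri} is not a DataStructure of this application"
            )
        return self.repo.resource_id(ds_iri)

    def live_instances(self, ds_iri):
        ds_id = self._check_data_structure(ds_iri)
        return sorted(store.instances_of(self.repo, ds_id))

    def _id_spec(self, ds_iri):
        for spec in self.specs(ds_iri):
            if spec.facets.is_id:
                return spec
        return None

    def _existing_id_values(self, ds_iri, id_spec, exclude=None):
        out = set()
        prop_id = self.repo.resource_id(id_spec.property_iri)
        for inst in self.live_instances(ds_iri):
            if inst == exclude:
                continue
            for tag, v in store.values_of(self.repo, inst).get(prop_id, []):
                out.add(str(v))
        return out

    def _resolve_option(self, spec, value):
        for opt in spec.options:
            if value in (opt.iri, opt.label) or (
                opt.code is not None and value == opt.code
            ):
                return opt.iri
        raise RejectionError(
            "OPTION_INVALID",
            f"value {value!r} is not an allowed option of "
            f"{local_name(spec.property_iri)}",
        )

    def _resolve_reference(self, spec, value):
        if isinstance(value, int):
            iri = self.repo.iri(value)
        else:
            iri = str(value)
        try:
            rid = self.repo.resource_id(iri)
        except UnknownResourceError as exc:
            raise RejectionError(
                "UNKNOWN_REFERENCE", f"referenced instance {iri} is not live"
            ) from exc
        if spec.target:
            target_id = self.repo.resource_id(spec.target)
            if rid not in store.instances_of(self.repo, target_id, transitive=True):
                raise RejectionError(
                    "TYPE_MISMATCH",
                    f"{iri} is not an instance of {local_name(spec.target)}",
                )
        return iri

    def _normalize_values(self, ds_iri, instance_iri, values):
        """Run the check pipeline; return {spec: [objects]} ready to assert.

        Check order: unknown fields, option membership, reference and type
        checks.  Mandatory and id-uniqueness checks are separate because
        their semantics differ between create and update.
        """
        specs_by_prop = {s.property_iri: s for s in self.specs(ds_iri)}
        menu_props = {
            p: None
            for p in self.graph.menu_properties()
            if self.graph.object(p, RDFS_DOMAIN) == ds_iri
        }
        out = {}
        for prop, raw in values.items():
            spec = specs_by_prop.get(prop)
            if spec is None and prop not in menu_props:
                raise RejectionError(
                    "UNKNOWN_FIELD", f"{prop} is not a field of {local_name(ds_iri)}"
                )
            items = raw if isinstance(raw, (list, tuple)) else [raw]
            objects = []
            for value in items:
                if value is None:
                    continue
                if spec is None:  # menu-linked child object
                    iri = (
                        self.repo.iri(value) if isinstance(value, int) else str(value)
                    )
                    objects.append(iri)
                elif spec.widget == "LiteralProperty":
                    raise RejectionError(
                        "TYPE_MISMATCH",
                        f"{local_name(prop)} is a literal display field and "
                        "takes no value",
                    )
                elif spec.value_type == "options":
                    objects.append(self._resolve_option(spec, value))
                elif spec.value_type == "resource":
                    objects.append(self._resolve_reference(spec, value))
                elif spec.widget == "Password":
                    objects.append(
                        Literal(
                            _password_digest(instance_iri, prop, str(value)),
                            "string",
                        )
                    )
                else:
                    _check_type(value, spec.value_type)
                    objects.append(_to_literal(value, spec.value_type))
            out[prop] = objects
        return out

    def _check_mandatory(self, ds_iri, provided):
        for spec in self.specs(ds_iri):
            if spec.widget == "LiteralProperty":
                continue
            if self.repo.is_deprecated(spec.property_iri):
                continue  # deprecated fields are no longer required
            raw = provided.get(spec.property_iri)
            missing = (
                raw is None
                or raw == ""
                or (isinstance(raw, (list, tuple)) and not raw)
            )
            if spec.facets.is_mandatory and missing:
                raise RejectionError(
                    "MANDATORY_MISSING",
                    f"mandatory field {local_name(spec.property_iri)} missing",
                )

    def _check_id_unique(self, ds_iri, normalized, exclude=None):
        id_spec = self._id_spec(ds_iri)
        if id_spec is None:
            return
        new = normalized.get(id_spec.property_iri) or []
        if not new:
            return
        lexical = new[0].lexical if isinstance(new[0], Literal) else str(new[0])
        if lexical in self._existing_id_values(ds_iri, id_spec, exclude=exclude):
            raise RejectionError(
                "ID_NOT_UNIQUE",
                f"id value {lexical!r} already used by a live instance",
            )

    # -- operations --------------------------------------------------------

    def create_instance(self, ds_iri: str, values: dict) -> int:
        """Create one instance; returns its resource id.

        Checks, in order: data structure live and not deprecated; mandatory
        fields present; id-field uniqueness; option membership; reference
        and datatype typing.  Any failure rejects with a coded error and
        leaves the repository unchanged.
        """
        ds_id = self._check_data_structure(ds_iri)
        if self.repo.is_deprecated(ds_iri):
            raise RejectionError(
                "DATA_STRUCTURE_DEPRECATED",
                f"{local_name(ds_iri)} is deprecated; new instances refused",
            )
        n = self.repo.next_counter("instance")
        instance_iri = f"{self.data_ns}{local_name(ds_iri)}_{n}"
        self._check_mandatory(ds_iri, values)
        normalized = self._normalize_values(ds_iri, instance_iri, values)
        self._check_id_unique(ds_iri, normalized)
        notification = None
        with self.repo.tx():
            store.assert_statement(
                self.repo, Statement(instance_iri, RDF_TYPE, ds_iri, self.data_ns)
            )
            for prop, objects in normalized.items():
                for obj in objects:
                    store.assert_statement(
                        self.repo, Statement(instance_iri, prop, obj, self.data_ns)
                    )
            instance_id = self.repo.resource_id(instance_iri)
            if self.graph.is_reportable(ds_iri):
                stamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
                self.repo.q(
                    "INSERT INTO notifications(data_structure_id, instance_id, "
                    "created_at) VALUES(?, ?, ?)",
                    ds_id,
                    instance_id,
                    stamp,
                )
                notification = Notification(ds_iri, instance_id, stamp)
        if notification is not None and self.notify is not None:
            self.notify(notification)
        return instance_id

    def _instance_context(self, instance_id: int):
        row = self.repo.one(
            "SELECT deleted FROM resources WHERE id = ?", instance_id
        )
        if row is None or row[0]:
            raise UnknownResourceError(
                f"instance {instance_id} unknown or deleted"
            )
        for (cid,) in self.repo.q(
            "SELECT class_id FROM instances WHERE instance_id = ? AND deleted = 0",
            instance_id,
        ):
            iri = self.repo.iri(cid)
            if iri in self.graph.instances(DATA_STRUCTURE):
                return self.repo.iri(instance_id), iri
        raise UnknownResourceError(
            f"instance {instance_id} is not a live data-structure instance"
        )

    def current_values(self, instance_id: int) -> dict:
        """Live values of an instance keyed by property IRI."""
        instance_iri, ds_iri = self._instance_context(instance_id)
        out = {}
        for prop_id, vals in store.values_of(self.repo, instance_id).items():
            prop_iri = self.repo.iri(prop_id)
            resolved = []
            for tag, v in vals:
                resolved.append(self.repo.iri(v) if tag == "resource" else v)
            out[prop_iri] = sorted(resolved, key=str)
        return out

    def update_instance(self, instance_id: int, values: dict) -> dict:
        """Update fields of a live instance; same checks as creation.

        Id uniqueness is re-checked only when the id value changes.  Edits
        to edition-disabled or deprecated fields are rejected unless the
        value is unchanged (a no-op update always succeeds).
        """
        instance_iri, ds_iri = self._instance_context(instance_id)
        specs_by_prop = {s.property_iri: s for s in self.specs(ds_iri)}
        normalized = self._normalize_values(ds_iri, instance_iri, values)
        current = self.current_values(instance_id)

        def as_comparable(objs):
            out = []
            for o in objs:
                if isinstance(o, Literal):
                    try:
                        out.append(str(store._coerce(o.lexical, o.datatype)))
                    except (ValueError, TypeError):
                        out.append(o.lexical)
                else:
                    out.append(str(o))
            return sorted(out)

        changed = {}
        for prop, objects in normalized.items():
            old = [str(v) for v in current.get(prop, [])]
            if as_comparable(objects) == sorted(old):
                continue
            spec = specs_by_prop.get(prop)
            if spec is not None and spec.facets.edition_disabled:
                raise RejectionError(
                    "EDITION_DISABLED",
                    f"field {local_name(prop)} is locked against edits",
                )
            if spec is not None and self.repo.is_deprecated(prop):
                raise RejectionError(
                    "FIELD_DEPRECATED",
                    f"field {local_name(prop)} is deprecated (read-only)",
                )
            if spec is not None and spec.facets.is_mandatory and not objects:
                raise RejectionError(
                    "MANDATORY_MISSING",
                    f"mandatory field {local_name(prop)} cannot be cleared",
                )
            changed[prop] = objects
        id_spec = self._id_spec(ds_iri)
        if id_spec is not None and id_spec.property_iri in changed:
            self._check_id_unique(ds_iri, normalized, exclude=instance_id)
        summary = {"changed": sorted(changed), "asserted": 0, "retracted": 0}
        if not changed:
            return summary
        with self.repo.tx():
            for prop, objects in changed.items():
                for old_stmt in self._live_value_statements(
                    instance_iri, instance_id, prop
                ):
                    store.retract_statement(self.repo, old_stmt)
                    summary["retracted"] += 1
                for obj in objects:
                    store.assert_statement(
                        self.repo, Statement(instance_iri, prop, obj, self.data_ns)
                    )
                    summary["asserted"] += 1
        return summary

    def _live_value_statements(self, instance_iri, instance_id, prop_iri=None):
        sql = (
            "SELECT rp.iri, ro.iri, s.object_lexical, s.object_datatype, "
            "s.object_kind, s.ontology_ns FROM statements s "
            "JOIN resources rp ON rp.id = s.predicate_id "
            "LEFT JOIN resources ro ON ro.id = s.object_id "
            "WHERE s.deleted = 0 AND s.subject_id = ?"
        )
        params = [instance_id]
        rows = []
        for p_iri, o_iri, lex, dtag, okind, ns in self.repo.q(sql, *params):
            if prop_iri is not None and p_iri != prop_iri:
                continue
            obj = Literal(lex, dtag) if okind == "literal" else o_iri
            rows.append(Statement(instance_iri, p_iri, obj, ns))
        return rows

    def _dependent_properties(self):
        out = set()
        for ds in self.graph.data_structures():
            for spec in self.specs(ds):
                if spec.facets.directly_dependent:
                    out.add(spec.property_iri)
        for prop in self.graph.menu_properties():
            if self.graph.facet_bool(prop, WEB_DIRECTLY_DEPENDENT):
                out.add(prop)
        return out

    def delete_instance(self, instance_id: int) -> dict:
        """Soft-delete an instance and, recursively, its dependent objects.

        The flagged set is the transitive closure over values of
        dependent-marked object properties; physical rows are retained.
        """
        self._instance_context(instance_id)  # raises if not live
        dependent_props = {
            self.repo.resource_id(p) for p in self._dependent_properties()
        }
        closure = []
        seen = {instance_id}
        frontier = [instance_id]
        while frontier:
            current = frontier.pop(0)
            closure.append(current)
            values = store.values_of(self.repo, current)
            for prop_id, vals in values.items():
                if prop_id not in dependent_props:
                    continue
                for tag, v in vals:
                    if tag == "resource" and v not in seen:
                        row = self.repo.one(
                            "SELECT deleted FROM resources WHERE id = ?", v
                        )
                        if row is not None and not row[0]:
                            seen.add(v)
                            frontier.append(v)
        with self.repo.tx():
            for inst in closure:
                inst_iri = self.repo.iri(inst)
                for stmt in self._live_value_statements(inst_iri, inst):
                    store.retract_statement(self.repo, stmt)
        return {"flagged": sorted(closure)}

    def list_instances(self, ds_iri: str):
        """Live instances with their description-field values.

        Returns (column property IRIs, rows); each row is
        (instance id, [column values]).
        """
        self._check_data_structure(ds_iri)
        columns = [
            s.property_iri
            for s in self.specs(ds_iri)
            if s.facets.is_description
        ]
        rows = []
        for inst in self.live_instances(ds_iri):
            values = self.current_values(inst)
            rows.append(
                (inst, [", ".join(str(v) for v in values.get(c, [])) for c in columns])
            )
        return columns, rows

    def notification_count(self) -> int:
        return self.repo.one("SELECT COUNT(*) FROM notifications")[0]

    # -- audit -------------------------------------------------------------

    def audit(self) -> list:
        """Independent whole-repository constraint audit.

        Re-reads every live instance's typed values straight from the value
        tables and re-checks every facet constraint; returns a list of
        violation strings (empty when the repository is sound).
        """
        violations = []
        for ds in self.graph.data_structures():
            specs = self.specs(ds)
            id_values = {}
            for inst in self.live_instances(ds):
                values = store.values_of(self.repo, inst)
                by_iri = {
                    self.repo.iri(pid): vals for pid, vals in values.items()
                }
                for spec in specs:
                    prop = spec.property_iri
                    vals = by_iri.get(prop, [])
                    if spec.widget == "LiteralProperty":
                        if vals:
                            violations.append(
                                f"{inst}: literal field {prop} holds values"
                            )
                        continue
                    if (
                        spec.facets.is_mandatory
                        and not self.repo.is_deprecated(prop)
                        and not vals
                    ):
                        violations.append(
                            f"{inst}: mandatory field {prop} is empty"
                        )
                    if spec.facets.is_id and vals:
                        lex = str(vals[0][1])
                        id_values.setdefault(lex, []).append(inst)
                    if spec.value_type == "options" and vals:
                        allowed = {o.iri for o in spec.options}
                        for tag, v in vals:
                            if tag != "resource" or self.repo.iri(v) not in allowed:
                                violations.append(
                                    f"{inst}: value of {prop} outside options"
                                )
                    elif spec.value_type not in ("options", "resource"):
                        for tag, v in vals:
                            if tag != spec.value_type and not (
                                tag == "string" and spec.value_type == "string"
                            ):
                                violations.append(
                                    f"{inst}: value of {prop} hosted in {tag} "
                                    f"table, declared {spec.value_type}"
                                )
            for lex, insts in id_values.items():
                if len(insts) > 1:
                    violations.append(
                        f"duplicate id value {lex!r} in {ds}: {insts}"
                    )
        return violations


def deprecate(repo: store.Repository, iri: str, flag: bool = True):
    """Set the deprecated flag on a class or property resource."""
    repo.deprecate(iri, flag)
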