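"""Form compilation, JSON rendering, and constraint-enforcing CRUD."""

import json
import pathlib
import random

import networkx as nx
import pytest

from ontoregistry import forms
from ontoregistry import store as S
from ontoregistry.exceptions import (
    RejectionError,
    UnknownResourceError,
    ValidationFailedError,
)
from ontoregistry.fixtures import caps_registry, populate_instances
from ontoregistry.owl_core import StatementSet

NS = "https://example.org/registry/caps#"
DATA_DIR = pathlib.Path(__file__).parent.parent / "src" / "ontoregistry" / "data"


class TestCompile:
    def test_menu_contains_registry_sections(self, caps_app):
        model = forms.compile_forms(caps_app)
        labels = {e.label for e in model.menu}
        assert {
            "Previous_Manifestations",
            "Precipitating_Factors",
            "Clinical_Manifestations",
        } <= labels

    def test_every_menu_leaf_resolves_to_a_form(self, caps_app):
        model = forms.compile_forms(caps_app)
        for entry in model.menu:
            assert entry.target in model.forms

    def test_grids_are_collision_free(self, caps_app):
        model = forms.compile_forms(caps_app)
        for fields in model.forms.values():
            cells = [(f.row, f.col) for f in fields]
            assert len(cells) == len(set(cells))

    def test_compile_twice_renders_byte_identically(self, caps_app):
        a = forms.render_form_model(forms.compile_forms(caps_app))
        b = forms.render_form_model(forms.compile_forms(caps_app))
        assert a == b

    def test_invalid_application_refused_with_report(self):
        with pytest.raises(ValidationFailedError) as err:
            forms.compile_forms(StatementSet())
        assert err.value.report.errors

    def test_json_round_trip_and_schema_sync(self, caps_app):
        model = forms.compile_forms(caps_app)
        text = forms.render_form_model(model)
        assert forms.parse_form_model(text) == model
        shipped = json.loads((DATA_DIR / "form_model.schema.json").read_text())
        assert shipped == forms.form_model_json_schema()

    def test_empty_model_renders(self):
        model = forms.FormModel(application="")
        parsed = forms.parse_form_model(forms.render_form_model(model))
        assert parsed.forms == {}

    def test_html_rendering_mentions_every_form(self, caps_app):
        model = forms.compile_forms(caps_app)
        html = forms.render_html(model)
        for ds in model.forms:
            assert ds.rsplit("#", 1)[-1] in html


class TestCreate:
    def _minimal_case(self, n=1):
        return {
            NS + "case_id": f"CAPS-{n:04d}",
            NS + "sex": "Male",
        }

    def test_create_and_read_back(self, caps_repo):
        reg = forms.Registry(caps_repo, NS)
        iid = reg.create_instance(NS + "case", {
            **self._minimal_case(), NS + "age": 44,
        })
        values = reg.current_values(iid)
        assert values[NS + "age"] == [44]
        assert values[NS + "sex"] == [NS + "Male"]

    def test_missing_mandatory_rejected(self, caps_repo):
        reg = forms.Registry(caps_repo, NS)
        with pytest.raises(RejectionError) as err:
            reg.create_instance(NS + "case", {NS + "case_id": "X"})
        assert err.value.code == "MANDATORY_MISSING"

    def test_duplicate_id_rejected(self, caps_repo):
        reg = forms.Registry(caps_repo, NS)
        reg.create_instance(NS + "case", self._minimal_case(1))
        with pytest.raises(RejectionError) as err:
            reg.create_instance(NS + "case", self._minimal_case(1))
        assert err.value.code == "ID_NOT_UNIQUE"

    def test_option_outside_list_rejected(self, caps_repo):
        reg = forms.Registry(caps_repo, NS)
        values = self._minimal_case()
        values[NS + "sex"] = "Unknown"
        with pytest.raises(RejectionError) as err:
            reg.create_instance(NS + "case", values)
        assert err.value.code == "OPTION_INVALID"

    def test_type_mismatch_rejected(self, caps_repo):
        reg = forms.Registry(caps_repo, NS)
        values = {**self._minimal_case(), NS + "age": "forty"}
        with pytest.raises(RejectionError) as err:
            reg.create_instance(NS + "case", values)
        assert err.value.code == "TYPE_MISMATCH"

    def test_rejection_leaves_repository_unchanged(self, caps_repo):
        reg = forms.Registry(caps_repo, NS)
        state = S.structural_state(caps_repo)
        rows = S.physical_row_count(caps_repo)
        with pytest.raises(RejectionError):
            reg.create_instance(NS + "case", {NS + "case_id": "X"})
        assert S.structural_state(caps_repo) == state
        assert S.physical_row_count(caps_repo) == rows

    def test_password_stored_as_digest(self, caps_repo):
        reg = forms.Registry(caps_repo, NS)
        iid = reg.create_instance(NS + "case", {
            **self._minimal_case(), NS + "access_code": "hunter2",
        })
        stored = reg.current_values(iid)[NS + "access_code"][0]
        assert stored.startswith("sha256$") and "hunter2" not in stored

    def test_reportable_creation_emits_exactly_one_notification(self, caps_repo):
        events = []
        reg = forms.Registry(caps_repo, NS, notify=events.append)
        reg.create_instance(NS + "Clinical_Manifestations", {
            NS + "cm_id": "CM-1", NS + "organ": "Kidney",
        })
        reg.create_instance(NS + "treatment", {NS + "drug": "heparin"})
        assert len(events) == 1
        assert events[0].data_structure == NS + "Clinical_Manifestations"
        assert reg.notification_count() == 1

    def test_deprecated_structure_blocks_creation(self, caps_repo):
        reg = forms.Registry(caps_repo, NS)
        caps_repo.deprecate(NS + "treatment")
        with pytest.raises(RejectionError) as err:
            reg.create_instance(NS + "treatment", {NS + "drug": "aspirin"})
        assert err.value.code == "DATA_STRUCTURE_DEPRECATED"

    def test_deprecated_field_no_longer_mandatory(self, caps_repo):
        reg = forms.Registry(caps_repo, NS)
        caps_repo.deprecate(NS + "sex")
        iid = reg.create_instance(NS + "case", {NS + "case_id": "C-1"})
        assert NS + "sex" not in reg.current_values(iid)


class TestUpdateDelete:
    @pytest.fixture()
    def reg(self, caps_registry_small):
        return caps_registry_small

    def test_noop_update_changes_nothing(self, reg):
        iid = reg.live_instances(NS + "case")[0]
        current = reg.current_values(iid)
        rows = S.physical_row_count(reg.repo)
        summary = reg.update_instance(iid, {NS + "age": current.get(NS + "age", [None])[0]})
        assert summary["asserted"] == summary["retracted"] == 0
        assert S.physical_row_count(reg.repo) == rows

    def test_update_then_read_back(self, reg):
        iid = reg.live_instances(NS + "case")[0]
        reg.update_instance(iid, {NS + "age": 99})
        assert reg.current_values(iid)[NS + "age"] == [99]
        assert S.structural_state(reg.repo) == S.rebuild_structural(reg.repo)

    def test_edit_disabled_field_rejected(self, reg):
        iid = reg.live_instances(NS + "case")[0]
        with pytest.raises(RejectionError) as err:
            reg.update_instance(iid, {NS + "registry_number": "changed"})
        assert err.value.code == "EDITION_DISABLED"

    def test_update_of_deleted_instance_rejected(self, reg):
        iid = reg.live_instances(NS + "treatment")[0]
        reg.delete_instance(iid)
        with pytest.raises(UnknownResourceError):
            reg.update_instance(iid, {NS + "dose_mg": 5})

    def test_delete_without_dependents_flags_exactly_one(self, reg):
        iid = reg.live_instances(NS + "treatment")[0]
        assert reg.delete_instance(iid)["flagged"] == [iid]

    def test_case_deletion_cascades_to_laboratory(self, reg):
        case = reg.live_instances(NS + "case")[0]
        lab_ids = {
            v for pid, vals in S.values_of(reg.repo, case).items()
            for tag, v in vals
            if tag == "resource"
            and reg.repo.iri(pid) == NS + "has_laboratory"
        }
        flagged = set(reg.delete_instance(case)["flagged"])
        assert flagged == {case} | lab_ids
        for lab in lab_ids:
            assert lab not in reg.live_instances(NS + "laboratory")

    def test_double_delete_errors(self, reg):
        iid = reg.live_instances(NS + "treatment")[0]
        reg.delete_instance(iid)
        with pytest.raises(UnknownResourceError):
            reg.delete_instance(iid)

    def test_list_counts_and_description_columns(self, reg):
        columns, rows = reg.list_instances(NS + "case")
        assert columns == [NS + "case_id", NS + "first_name"]
        n = len(rows)
        reg.delete_instance(rows[0][0])
        assert len(reg.list_instances(NS + "case")[1]) == n - 1


class TestCascadeOracle:
    def _node_app(self):
        """An application with one self-referencing dependent structure."""
        from ontoregistry import metamodel as mm
        from ontoregistry.namespaces import (
            OWL_CLASS, OWL_DATATYPE_PROPERTY, OWL_OBJECT_PROPERTY,
            OWL_ONTOLOGY, RDF_TYPE, RDFS_DOMAIN, RDFS_RANGE, RDFS_SUBCLASSOF,
            XSD_NS,
        )
        from ontoregistry.owl_core import Literal, Statement

        ns = "http://example.org/deps#"
        st = []
        add = lambda *a: st.append(Statement(*a, ns))
        add(ns[:-1], RDF_TYPE, OWL_ONTOLOGY)
        add(ns + "App", RDF_TYPE, mm.APPLICATION)
        add(ns + "Node", RDF_TYPE, mm.DATA_STRUCTURE)
        add(ns + "Node", RDF_TYPE, OWL_CLASS)
        add(ns + "Node", RDFS_SUBCLASSOF, mm.APPLICATION_ITEM)
        add(ns + "node_id", RDF_TYPE, OWL_DATATYPE_PROPERTY)
        add(ns + "node_id", RDF_TYPE, mm.WIDGET_IRIS["SingleCell"])
        add(ns + "node_id", RDFS_DOMAIN, ns + "Node")
        add(ns + "node_id", RDFS_RANGE, XSD_NS + "string")
        add(ns + "node_id", mm.WEB_ROW, Literal("1", "integer"))
        add(ns + "node_id", mm.WEB_COLUMN, Literal("1", "integer"))
        add(ns + "node_id", mm.WEB_ID, Literal("true", "boolean"))
        add(ns + "child", RDF_TYPE, OWL_OBJECT_PROPERTY)
        add(ns + "child", RDF_TYPE, mm.WIDGET_IRIS["SingleCell"])
        add(ns + "child", RDFS_DOMAIN, ns + "Node")
        add(ns + "child", RDFS_RANGE, ns + "Node")
        add(ns + "child", mm.WEB_ROW, Literal("2", "integer"))
        add(ns + "child", mm.WEB_COLUMN, Literal("1", "integer"))
        add(ns + "child", mm.WEB_DIRECTLY_DEPENDENT, Literal("true", "boolean"))
        return ns, StatementSet.from_statements(st, origin_ns=ns)

    def test_flagged_set_equals_reachability(self, repo):
        ns, app = self._node_app()
        S.upload_ontology(repo, app, mode="incremental")
        reg = forms.Registry(repo, ns)
        rng = random.Random(99)
        for trial in range(10):
            n = rng.randint(3, 12)
            ids = {}
            graph = nx.DiGraph()
            for node in range(n - 1, -1, -1):  # children before parents
                kids = [ids[c] for c in range(node + 1, n)
                        if rng.random() < 0.3 and c in ids and ids[c] in reg.live_instances(ns + "Node")]
                values = {ns + "node_id": f"t{trial}-n{node}"}
                if kids:
                    values[ns + "child"] = kids
                ids[node] = reg.create_instance(ns + "Node", values)
                graph.add_node(ids[node])
                for k in kids:
                    graph.add_edge(ids[node], k)
            root = ids[0]
            expected = {root} | set(nx.descendants(graph, root))
            expected &= set(reg.live_instances(ns + "Node"))
            flagged = set(reg.delete_instance(root)["flagged"])
            assert flagged == expected


class TestConstraintSoundness:
    def test_random_accepted_mutations_keep_repository_clean(self, caps_registry_small):
        reg = caps_registry_small
        rng = random.Random(5)
        structures = reg.graph.data_structures()
        for _ in range(120):
            action = rng.random()
            ds = rng.choice(structures)
            live = reg.live_instances(ds)
            try:
                if action < 0.5 or not live:
                    values = {}
                    for spec in reg.specs(ds):
                        if spec.facets.is_id:
                            values[spec.property_iri] = f"r{rng.randrange(10**9)}"
                        elif spec.facets.is_mandatory:
                            values[spec.property_iri] = _value_for(rng, spec)
                    reg.create_instance(ds, values)
                elif action < 0.8:
                    iid = rng.choice(live)
                    editable = [
                        s for s in reg.specs(ds)
                        if not (s.facets.edition_disabled or s.facets.is_id
                                or s.widget in ("LiteralProperty", "Password")
                                or s.value_type == "resource")
                    ]
                    if editable:
                        spec = rng.choice(editable)
                        reg.update_instance(
                            iid, {spec.property_iri: _value_for(rng, spec)}
                        )
                else:
                    reg.delete_instance(rng.choice(live))
            except RejectionError:
                pass
        assert reg.audit() == []
        assert S.structural_state(reg.repo) == S.rebuild_structural(reg.repo)


def _value_for(rng, spec):
    import datetime

    kind = spec.value_type
    if kind == "options":
        return rng.choice(spec.options).iri
    if kind == "integer":
        return rng.randint(0, 99)
    if kind == "float":
        return round(rng.uniform(0, 9), 2)
    if kind == "boolean":
        return rng.random() < 0.5
    if kind == "date":
        return datetime.date(2020, 1, 1) + datetime.timedelta(days=rng.randint(0, 999))
    if kind == "datetime":
        return datetime.datetime(2020, 1, 1, 12, 0)
    return f"s{rng.randrange(10**6)}"
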