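# ontoregistry

An ontology-driven engine for clinical data registries and case report
forms. Both the data model and the data-entry interface of a registry are
declared in an OWL ontology written against a built-in metamodel; no
database design or per-project programming is needed. The engine stores
models and captured data in one generic relational repository, compiles
the declared forms into renderable JSON bundles, enforces the declared
constraints during data entry, and extracts the captured data as XML
documents or a relational SQL mirror for statistical analysis.

It is aimed at research groups who run many small-to-medium registries —
a few hundred to a couple of thousand cases, tens to hundreds of
variables per case — and need to stand up a new study, or change a
running one, by editing an ontology rather than a schema.

## The model

**Declarative applications.** An application is an instance of the
metaclass `Application`. Each data-entry form is a class that is an
instance of the metaclass `DataStructure` and a subclass of
`ApplicationItem`; its properties are the form fields. A field's widget
is fixed by typing the property with one of the eleven `FormElement`
subclasses (`SingleCell`, `Combobox`, `RadioButton`, `Checkbox`,
`MultilineStringProperty`, `Password`, `Graphic`, `HyperlinkProperty`,
`ImageProperty`, `LiteralProperty`, `SubForm`), and its behavior by the
facet properties `webRow`/`webColumn` (grid position),
`webDescriptionProperty`, `webMandatoryProperty`, `webIdProperty`
(mandatory + unique), `webEditionDisabled` and `webDirectlyDependent`
(values that cannot outlive their owner — cascade on delete). Constrained
fields point to a subclass of `AllowedValues` (or `CodedValues` for
options with attached codes) whose ranked individuals are the permitted
options. Object properties typed `MenuItem` both link the case root to
its satellite forms and define the navigation menu. Classes subclassing
`Reportable` emit a notification on every instance creation.

**Hybrid relational storage.** The repository is neither one triple table
nor one table per class: it keeps a single statements table holding every
asserted subject–predicate–object triple *and* one table per
ontology-language metaclass role (resource, class, property, domain,
range, subsumption, instance-of), with property values split into one
table per supported datatype (string, integer, float, boolean, date,
datetime, resource). The statements table is the interface: asserting or
retracting a statement propagates, inside the same transaction, to the
structural tables, whose live content therefore always equals a
from-scratch rebuild over the live statements. Resources are identified
by short surrogate integer ids that are never reused, and nothing is
ever physically deleted — every table carries a delete flag, so the
physical row count only grows.

**Nested-set hierarchy index.** Transitive queries (all subclasses of a
class, all instances at any depth) are answered without recursion: each
node of the subsumption tree is labeled with a (left, right) integer
interval such that the descendants of a node are exactly the nodes whose
left label falls strictly inside its interval. Multiple inheritance is
handled by duplicating the multi-parent node (and, recursively, its
subtree) under each parent, with query results collapsed back to
canonical resources. The index is built in one batch pass after a bulk
load — not per inserted class — which keeps taxonomies in the
10,000-class range practical.

## Worked example

```python
from ontoregistry import init_repository, upload_ontology, Registry, run_extractions
from ontoregistry.fixtures import caps_registry, populate_instances

repo = init_repository("caps.db")          # schema + metamodel pre-loaded
app = caps_registry()                      # a CAPS-like case registry ontology
upload_ontology(repo, app, mode="incremental")
ns = app.origin_ns

populate_instances(repo, ns, n_cases=3, seed=42)
registry = Registry(repo, ns)

columns, rows = registry.list_instances(ns + "case")
print("columns:", [c.rsplit("#", 1)[-1] for c in columns])
for instance_id, values in rows:
    print(instance_id, values)

case_id = rows[0][0]
print("cascade:", registry.delete_instance(case_id))

xml = run_extractions(repo, ns)["extract_laboratory"]
print("records:", xml.count("<record"))
```

prints

```
columns: ['case_id', 'first_name']
110 ['case-00001-0', 'text 730044']
119 ['case-00002-0', 'text 173776']
128 ['case-00003-0', 'text 43351']
cascade: {'flagged': [108, 110]}
records: 4
```

The instance list shows only the fields flagged as description columns.
Deleting case `110` also flags its laboratory result `108` (laboratory
records are declared directly dependent on their case), and the
laboratory extraction afterwards holds the 4 results still live. A
creation on the reportable `Clinical_Manifestations` form would
additionally emit exactly one notification.

The same operations are available from the shell:

```sh
ontoregistry init --repo caps.db
ontoregistry load --repo caps.db caps.owl --mode replace
ontoregistry validate caps.owl
ontoregistry compile-forms --repo caps.db --ns 'https://example.org/registry/caps#'
ontoregistry extract-xml --repo caps.db --ns '…#' --out-dir exports/
ontoregistry export-sql  --repo caps.db --ns '…#' mirror.sql
```

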