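# Methods

This note documents the engine's design: the storage and indexing model,
the metamodel and its validation rules, the CRUD constraint semantics,
the extraction formats, what the synthetic generators emulate, and the
numerical/design choices made where more than one behavior was
defensible.

## Storage model

The repository is a hybrid between a schema-oblivious triple store and a
schema-aware one-table-per-class design. A single **statements table**
holds every asserted triple — `(subject_id, predicate_id, object, origin
namespace, deleted)` with literal objects stored inline as a lexical form
plus a datatype tag, one of {string, integer, float, boolean, date,
datetime}. Alongside it, **structural tables** materialize the
ontology-language roles: `resources` (surrogate id ↔ IRI), `classes`,
`properties`, `domains`, `ranges`, `subsumption` (subclass-of and
subproperty-of edges), `instances`, `imports`, `ontologies`, and one
**value table per datatype** plus one for resource-valued properties.

The statements table is the interface. Asserting or retracting a
statement triggers propagation to the structural tables inside the same
transaction; the implementation is application-level rather than
database triggers, but the observable contract is the trigger one, and it
is stated as an invariant: *at any point, the live structural rows equal
what a from-scratch rebuild over the live statements produces*
(`rebuild_structural` is that pure rebuild, and doubles as the oracle in
the test suite). To keep the invariant exact under arbitrary orderings:

- every structural row is derivable from the live statement set alone;
  on retract, a row is only flagged deleted after re-checking that no
  other live statement still supports it (a class, for instance, is
  supported by explicit typing, by either side of a subclass axiom, by
  being the type of an instance, or by appearing as a domain/range);
- the same triple asserted in two namespaces supports its derived rows
  twice; retracting one occurrence changes nothing structurally;
- a literal value is hosted in the table named by the property's declared
  datatype range; if the range is declared (or retracted) *after* values
  exist, all value rows of that property are re-placed. Properties with
  no declared range default to the string table with a validation
  warning, and a literal that does not parse under the declared range
  also falls back to string with a warning rather than failing a bulk
  load. With several datatype ranges declared, the lexicographically
  smallest tag wins (a deterministic tie-break; multiple ranges are
  ill-formed input).

Consistency guards mirror what an ontology editor refuses: typing a
resource as both a class and a property is rejected with the statements
table unchanged; retracting the class typing of a class with live
instances is refused; symmetrically (our extrapolation) retracting the
property typing of a property with live values is refused.

Soft delete is universal: no API call ever removes a physical row, so the
total physical row count is monotonically non-decreasing. The one
exception by design is the hierarchy index (below), which is derived data
rebuilt wholesale and is therefore excluded from the conservation
accounting, as are the `meta` and `counters` bookkeeping tables.
Resource ids are issued by the database sequence and never reused; a
re-asserted statement revives its original row and ids.

Comparisons between the incremental state and the rebuild cover all
structural tables and the live-resource set. The `resources.kind` column
is maintained opportunistically for inspection and is not part of the
equality contract.

### Two ingestion paths

`upload_ontology` is the editor path: statements are applied one by one
through the guarded propagation machinery (mode `replace` first
soft-deletes the namespace's statements absent from the new set — which
is where the class-with-instances guard protects captured data — mode
`incremental` only applies additions), and the hierarchy index is rebuilt
once at the end. `ontoload` is the bulk path: statements are inserted
directly into the statements table in one transaction, then one
structural rebuild and one hierarchy batch build run at the end; a parse
failure persists nothing. The two paths are required to produce identical
final states, and the acceptance suite checks exactly that — they share
the statement-preparation step but not the application machinery.

Instance data captured through the CRUD API is stored under a data
namespace derived from the application namespace (`…/app` →
`…/app/data#`), so replacing a model ontology never touches captured
data.

## Nested-set hierarchy index

Subsumption trees are labeled depth-first with consecutive integers:
each placement gets a (left, right) interval, children are visited in
ascending resource-id order (making labels a pure function of the edge
set), and a pure tree of N placements uses exactly the labels 1..2N.
Descendant queries are interval containment on the left-sorted placement
list; ancestor queries are the dual containment test. Both operate
without recursion.

Multiple inheritance is resolved by duplication: a resource with k
parents is placed once under each parent, and each placement carries a
recursively duplicated copy of the resource's subtree — full recursive
duplication is required for interval queries to remain correct at every
level. Queries collapse duplicates to canonical resource ids; raw
placements are reachable only through a debug accessor. Duplication
costs storage proportional to the number of parent-paths, which is
negligible at the observed multiparent rates (a few percent).

Single-resource insertion supports two policies: `relabel_incremental`
shifts the labels at or above each insertion point by 2 (inserting at
the position ascending-id order dictates, so that any sequence of
incremental inserts reproduces the batch labeling exactly), and
`mark_stale`, which defers to the next batch rebuild and makes queries
refuse to answer in between. The repository itself uses the batch
policy: subsumption-changing statements mark the index stale and the
next transitive query (or an explicit `rebuild-index`) rebuilds it in
one pass. This is the scalability-critical choice: relabeling on every
class insertion is quadratic in the hierarchy size, while one batch
build over a ~16,000-class taxonomy takes well under a second in this
implementation.

## Metamodel and validation

The built-in vocabulary (shipped both programmatically and as a
versioned RDF/XML file under `ontoregistry/data/`) declares: metaclasses
`Application`, `DataStructure`, `Reportable`; classes `ApplicationItem`,
`MenuItem`, `FormElement` with its eleven widget subclasses,
`OrderedItem` ⊇ `AllowedValues` ⊇ `CodedValues`, `DataExtraction`; the
seven `web*` facet properties; `itemOrder` (integer rank of options),
`code` (string code of coded options), and `extractionTarget` /
`extractionRecursive`. The access-control classes (`Role`,
`UnderAuthorization`, `Organization`, `Authorization`) are declared so
ontologies using them parse, but no access semantics are enforced.

`validate_application` evaluates eleven coded rules (plus
`LAYOUT_MISSING` for fields without a grid position — rendering is
impossible without one, so absence of `webRow`/`webColumn` is an error,
while the boolean facets default to false):

| code | rule |
|---|---|
| `APP_MISSING` | at least one `Application` instance |
| `FORM_NOT_APPLICATION_ITEM` | every `DataStructure` instance subclasses `ApplicationItem` |
| `FIELD_WIDGET_COUNT` | every field has exactly one widget type |
| `MENU_MALFORMED` | menu entries are object properties linking DataStructures |
| `GRID_COLLISION` | no two fields of a form share (row, column) |
| `OPTIONS_MISSING` | Combobox/RadioButton fields reference an `AllowedValues` subclass with ≥1 option |
| `CODE_MISSING` | every coded option carries a code |
| `ORDER_MISSING` | every option carries an integer rank |
| `SUBFORM_UNSUPPORTED` | SubForm fields warn (accepted, skipped by the compiler) |
| `DEPENDENT_NOT_OBJECT` | the cascade facet only on object properties |
| `ID_FIELD_DUPLICATE` | at most one id field per DataStructure |

All findings are collected into a JSON-serializable report; nothing
raises. Every rule has a single-mutation fixture
(`fixtures.validator_mutations`) that triggers exactly that rule and no
other — the fault-injection map is itself shipped and checked, so the
rule set cannot silently lose coverage.

Decisions where the design was open: grid coordinates are 1-based; the
option rank is an integer-valued property with ties broken by IRI
lexical order; the code of a coded option is a string-valued `code`
property; id-field uniqueness is scoped per DataStructure (not per
application); `AllowedValues` is a subclass of `OrderedItem` (options
inherit orderability); menu labels are taken from the target form's
local name.

## Forms and CRUD semantics

`compile_forms` turns a validated application into a deterministic JSON
document (schema shipped, generated from the pydantic model and kept in
sync by a test): the menu, one collision-free field grid per form, and
the description columns used by instance lists. SubForm fields compile
to nothing. An optional static HTML rendering exists for inspection;
serving forms is out of scope by design — the JSON bundle is the
interface for any front end.

Instance mutations run a fixed check pipeline — mandatory fields, id
uniqueness, option membership, reference and datatype typing — in that
order, each failure a distinct coded rejection, and any rejection leaves
live content and physical row counts unchanged. Updates re-check id
uniqueness only when the id value changes, reject edits to
edition-disabled or deprecated fields unless the value is unchanged (a
no-op update always succeeds), and refuse to clear a mandatory field.
Creation on a deprecated DataStructure is refused; deprecated fields
stop being required and become read-only (reads of existing values stay
available). Password field values are stored as salted SHA-256 digests
— the salt derived deterministically from the instance and property
IRIs so seeded populations reproduce — and never appear in any export.
Graphic/Hyperlink/Image values are stored as string references, never
binary payloads.

Deletion flags the instance and, recursively, every instance reachable
over values of properties carrying the dependent-cascade facet; the
flagged set is defined as (and tested against) transitive reachability.
A parent's link to a directly deleted child remains in the statements
table but is invisible to lists, extractions and the audit, all of which
key on live instance-of rows.

Creations on `Reportable` subclasses record exactly one notification row
and invoke an optional callback after commit; delivery (e-mail or
otherwise) is a host-system concern behind that hook.

`Registry.audit` is the independent soundness check: it re-reads every
live instance's typed values straight from the value tables and
re-evaluates every facet constraint, sharing none of the mutation-path
code.

## Extraction

XML extraction executes the application's `DataExtraction` instances:
one document per spec, one `record` element per live instance of the
target, fields as child elements in grid order. Option values are
emitted as label text with a `code` attribute when coded (both, since
printed codebooks need either). With `recursive=true`, object values
inline the referenced record, each instance expanded at most once per
document — repeats and cycles degrade to `ref="<id>"` attributes — and
with `recursive=false` only references are emitted. Multi-valued
properties repeat the element.

The SQL mirror emits one table per DataStructure (primary key = the
instance's surrogate id), one column per datatype field (types:
VARCHAR/INTEGER/DOUBLE PRECISION/SMALLINT/CHAR(10)/VARCHAR(32)), option
fields as a label column plus a `_code` column for coded lists, and one
link table per object property (object links are treated as potentially
multi-valued; a functional declaration would be honored as a foreign-key
column but the generators do not emit one). Identifiers are mangled to
lower-cased alphanumerics-and-underscores and double-quoted in the
script, so reserved words like `case` are safe; mangling collisions are
an error listing the colliding classes. Scripts are deterministic,
executable on an empty SQL-92 database, and one-shot — re-execution
fails on the duplicate keys, by design, because each script is a
snapshot.

## Synthetic data

The generators make every module testable without external data, and
their defaults are chosen to mirror the deployments this class of system
reports: registries of a few hundred to 2,000 cases with roughly 60–600
variables per case (default: 8 data structures × 6–12 fields ≈ 70
variables, 300 cases), and taxonomies up to the ~16,000-class range for
the hierarchy stress preset. `generate_registry` emits a case root with
menu-linked satellite forms, cycling field widgets through the complete
vocabulary so every widget and facet occurs under defaults; fractions of
the satellites are reportable (0.25) and dependent (0.4), and option
lists mix plain and coded. `populate_instances` enters data exclusively
through the CRUD pipeline — uniform draws over options, bounded uniform
integers/floats, ISO dates in a fixed window — so a successful
population is by construction constraint-clean; value *distributions*
carry no clinical realism and are not meant to. `generate_hierarchy`
grows a rooted tree under depth/branching limits and then gives a
fraction of nodes (default 0.1) one extra, always-earlier parent,
guaranteeing acyclicity. Everything is seed-deterministic: equal seeds
give byte-identical serialized fixtures.

What passing tests on these fixtures shows is that the *machinery* is
sound — storage equivalences, constraint enforcement, cascade and
counting exactness. What they cannot show is robustness to the mess of
real ontologies (annotation-heavy models, OWL constructs outside the
asserted-statement fragment, non-ASCII identifier conventions) or
realistic data distributions.

## Numerical and format choices

- Canonical statement order is the lexicographic (subject, predicate,
  object) sort; RDF/XML serialization is a flat, hand-written writer so
  that equal statement sets serialize byte-identically (the round-trip
  and determinism contracts are tested at the byte level). Turtle is a
  convenience dialect on input and output.
- Blank nodes are accepted on input and skolemized to stable labels
  derived from a content signature; round-trip equality is defined
  modulo blank-node relabeling. The storage layer namespaces blank
  labels per ontology to avoid cross-ontology collisions.
- The supported literal datatypes are the closed set {string, integer,
  float, boolean, date, datetime}; anything else is rejected at parse
  time naming the offending datatype. Common XSD aliases (`int`,
  `long`, `decimal`, `double`, …) normalize into the set.
- The import closure is resolved through a caller-supplied resolver and
  loaded in topological order, imported ontologies before importers;
  cycles and unresolvable imports are errors naming the culprits.
- OWL species checking is out of scope: any asserted-statement graph is
  accepted.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run the full-scale checks:
50 registry round trips, 200 propagation sequences (pools up to ~500
statements), 1,000 random hierarchies (most 5–80 classes, a tail to
2,000, queries sampled at 30 nodes for the larger ones) plus one
15,982-class batch build, 20 ingestion-equivalence fixtures plus one
~100,000-statement bulk load, 1,000 accepted CRUD mutations with ~10%
injected faults, 100 cascade trees, and export/notification counting
over populated registries of 25 and 8 cases. On one CPU the whole
acceptance script completes in about a minute.

## Known limitations

- No reasoning, SPARQL, or SWRL; classification is rule-based over
  asserted statements only, and `owl:equivalentClass` is not merged.
- Single-writer: transactions are atomic but there is no multi-writer
  coordination.
- Access-control vocabulary is parsed, never enforced; there is no
  authentication.
- The nested-set duplication strategy is exponential in pathological
  DAGs (dense multi-inheritance); it is intended for the near-tree
  subsumption structures registries actually use.
- Edit semantics for instances of deprecated DataStructures: reads
  allowed, creations blocked, field edits follow the deprecated-field
  rule — one consistent choice among several defensible ones.
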