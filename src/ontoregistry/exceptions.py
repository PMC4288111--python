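"""Exception hierarchy shared by all layers of the engine."""


class OntoRegistryError(Exception):
    """Base class for all domain errors raised by this package."""


class ParseError(OntoRegistryError):
    """An OWL document could not be parsed in the declared dialect."""


class UnsupportedDialectError(OntoRegistryError):
    """A serialization dialect other than rdfxml/turtle was requested."""


class UnsupportedDatatypeError(OntoRegistryError):
    """A literal carries a datatype outside the supported closed set."""


class ImportCycleError(OntoRegistryError):
    """The owl:imports graph contains a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("import cycle: " + " -> ".join(self.cycle))


class UnresolvableImportError(OntoRegistryError):
    """An imported ontology IRI could not be resolved."""


class ContradictoryTypingError(OntoRegistryError):
    """A resource is typed into incompatible kinds (e.g. class and property)."""

    def __init__(self, resource, statements):
        self.resource = resource
        self.statements = list(statements)
        super().__init__(
            f"contradictory typing for {resource}: "
            + "; ".join(str(s) for s in self.statements)
        )


class SchemaError(OntoRegistryError):
    """Repository schema missing, corrupted or of an incompatible version."""


class UnknownResourceError(OntoRegistryError):
    """A resource id / IRI / namespace is unknown or soft-deleted."""


class GuardViolationError(OntoRegistryError):
    """A mutation was refused because it would leave the ontology inconsistent
    (e.g. deleting a class that still has live instances)."""


class HierarchyCycleError(OntoRegistryError):
    """The subsumption edge set contains a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(
            "subsumption cycle: " + " -> ".join(str(n) for n in self.cycle)
        )


class OrphanNodeError(OntoRegistryError):
    """A non-root resource has no parent path to any declared root."""


class StaleIndexError(OntoRegistryError):
    """A transitive query was attempted on a stale nested-set index."""


class ValidationFailedError(OntoRegistryError):
    """An operation requiring a valid application was given an invalid one."""

    def __init__(self, report):
        self.report = report
        codes = ", ".join(sorted({f.code for f in report.errors}))
        super().__init__(f"application ontology is invalid ({codes})")


class RejectionError(OntoRegistryError):
    """A CRUD mutation was rejected by a constraint check.

    ``code`` is a stable machine-readable identifier of the failed check.
    """

    def __init__(self, code, message):
        self.code = code
        super().__init__(f"{code}: {message}")


class NothingToExtractError(OntoRegistryError):
    """The application declares no extraction specifications."""


class NameCollisionError(OntoRegistryError):
    """SQL name mangling produced colliding identifiers, or a namespace is
    already bound to a different ontology IRI."""
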