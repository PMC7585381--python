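"""Exception hierarchy for the DNMSO library.

All library errors derive from :class:`DnmsoError` so callers (and the CLI)
can distinguish domain failures from programming errors.
"""


class DnmsoError(Exception):
    """Base class for all DNMSO errors."""


class IdentityConflictError(DnmsoError):
    """A local id is already taken within its collection."""


class StructuralError(DnmsoError):
    """An object violates a structural invariant of the data model."""


class OrphanPredictionError(StructuralError):
    """A prediction has no source spectra (forbidden by the model)."""


class MissingScoreError(StructuralError):
    """A prediction carries no score (at least one is mandatory)."""


class UnresolvedReferenceError(DnmsoError):
    """A local-id reference does not resolve within the document."""


class UnresolvedModificationError(UnresolvedReferenceError):
    """A modification accession or name has no match in the table."""


class AmbiguityError(DnmsoError):
    """A name query matched more than one modification."""


class AlphabetError(DnmsoError):
    """A residue letter is not one of the 20 standard amino acids."""


class SequenceSyntaxError(DnmsoError):
    """A textual sequence could not be parsed (unbalanced brackets etc.)."""


class SpectraParseError(DnmsoError):
    """A spectra file could not be parsed; message carries the location."""


class TruncationError(SpectraParseError):
    """A block-structured spectra file ended mid-block."""


class DialectError(DnmsoError):
    """A legacy results file does not follow the frozen dialect."""


class InvalidDocumentError(DnmsoError):
    """Serialization/export refused because the document has ERROR violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(f"{v.rule_id}@{v.element_id}" for v in self.violations)
        super().__init__(f"document is invalid: {lines}")


class RdfParseError(DnmsoError):
    """Input bytes are not parseable RDF in the declared dialect."""


class VersionError(DnmsoError):
    """An RDF graph uses an unknown or wrong-version DNMSO namespace."""


class QueryError(DnmsoError):
    """A SPARQL query failed to parse or execute."""
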