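"""Exception hierarchy.

Every error raised by galkit derives from :class:`GalkitError` so callers
(and the CLI) can distinguish validation problems from stage failures.
"""


class GalkitError(Exception):
    """Base class for all galkit errors."""


class ParseError(GalkitError):
    """A coordinate file could not be parsed."""


class EmptyStructureError(ParseError):
    """A coordinate file parsed but contained no atoms."""


class ChainNotFoundError(GalkitError, LookupError):
    """A requested chain is absent from the structure."""


class GlycanNotFoundError(GalkitError, LookupError):
    """No candidate sugar residues were found."""


class AmbiguousLinkageError(GalkitError):
    """Both O3 and O4 of GlcNAc are within bonding distance of C1 of Gal."""


class ResidueLookupError(GalkitError, LookupError):
    """A residue is not present in the correspondence map or structure."""


class MissingAtomError(GalkitError, LookupError):
    """A named atom required by an operation is missing."""


class DegenerateGeometryError(GalkitError):
    """Geometry is degenerate (collinear dihedral, rank-deficient fit...)."""


class UndefinedAverageError(GalkitError):
    """An average was requested over an empty set or a vanishing resultant."""


class FitError(GalkitError):
    """Nonlinear fit failed to converge or inputs violate preconditions."""


class NoCompetitionError(GalkitError):
    """Competition measurement shows no detectable competitor binding."""


class InconsistentInputsError(GalkitError):
    """Measurement values are mutually inconsistent (e.g. [C] <= 0)."""


class AnnotationError(GalkitError):
    """A sequence/loop annotation is invalid (index outside region...)."""


class FixtureError(GalkitError):
    """A synthetic fixture request cannot be satisfied."""


class PipelineError(GalkitError):
    """A pipeline stage failed; carries the stage name and input id."""

    def __init__(self, stage: str, input_id: str, message: str):
        super().__init__(f"stage '{stage}' failed on '{input_id}': {message}")
        self.stage = stage
        self.input_id = input_id


class ConfigError(GalkitError):
    """A run manifest or CLI configuration failed validation."""
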