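"""Exception hierarchy for pairlim.

Every error raised by the library derives from :class:`PairlimError` so that
callers (and the CLI) can distinguish pipeline failures from programming bugs.
"""


class PairlimError(Exception):
    """Base class for all pairlim errors."""


class FormatError(PairlimError):
    """A file does not conform to the expected CSV dialect."""


class ValidationError(PairlimError):
    """Input data violates a structural invariant (e.g. duplicate IDs)."""


class ParseError(PairlimError):
    """A cell could not be parsed as a number; carries row/column context."""


class AlignmentError(PairlimError):
    """Gene, metabolite and metadata sample sets cannot be aligned."""


class PhenotypeError(PairlimError):
    """The phenotype column is unusable (wrong number of levels, missing)."""


class MappingError(PairlimError):
    """A replicate or probe map refers to columns/features that do not exist."""


class DomainError(PairlimError):
    """A numeric argument is outside its valid domain."""


class LookupIDError(PairlimError, KeyError):
    """A requested feature or sample ID is not present."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class SpecError(PairlimError):
    """A synthetic-data specification is infeasible or inconsistent."""


class PipelineError(PairlimError):
    """A pipeline stage failed; message names the stage."""
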