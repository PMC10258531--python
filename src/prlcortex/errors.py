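"""Exception hierarchy.

Validation problems (bad parameters, malformed inputs) and computation
problems (degenerate fits, exhausted meshes) are kept on separate branches so
the CLI can map them to distinct exit codes.
"""


class PRLCortexError(Exception):
    """Base class for all package errors."""


class ValidationError(PRLCortexError):
    """Input files or parameters fail schema/precondition checks."""


class InvalidParameterError(ValidationError):
    pass


class EmptyInputError(ValidationError):
    pass


class UnbalancedDesignError(ValidationError):
    """A participant is missing within-factor levels; no imputation is done."""


class ComputationError(PRLCortexError):
    """A well-formed request that cannot be computed."""


class GenerationError(ComputationError):
    pass


class DegenerateFitError(ComputationError):
    pass


class AlignmentError(ComputationError):
    pass


class EmptyROIError(ComputationError):
    pass


class NoValidURLError(ComputationError):
    pass


class MissingAnnotationError(ComputationError):
    pass


class InsufficientSurfaceError(ComputationError):
    pass


class UncoveredVertexError(ComputationError):
    pass


class NormalizationError(ComputationError):
    pass


class EmptyAggregateError(ComputationError):
    pass


class DegenerateTestError(ComputationError):
    pass


class SingularMatrixError(ComputationError):
    pass


class CollinearityError(ComputationError):
    pass
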