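"""Exception hierarchy shared across the pipeline stages."""


class RaseffError(Exception):
    """Base class for all package-specific errors."""


class ChainNotFoundError(RaseffError):
    """A requested chain id does not occur in the selected model."""


class MalformedInputError(RaseffError):
    """Input text is structurally invalid (no models, no atoms, ...)."""


class AmbiguousChainError(RaseffError):
    """A chain sequence matches both the RAS and the effector side."""


class RaggedAlignmentError(RaseffError):
    """Alignment rows are not all the same length."""


class DuplicateRowError(RaseffError):
    """Two alignment rows share the same name."""


class SequenceMismatchError(RaseffError):
    """Structure chain sequence cannot be placed on its alignment row."""


class EmptyInputError(RaseffError):
    """An aggregation step received no structures / no files."""


class InsufficientDataError(RaseffError):
    """Too few titration points (or replicates) to fit."""


class DegenerateDataError(RaseffError):
    """Titration signals carry no information (all equal)."""


class SpecConflictError(RaseffError):
    """A synthetic-data specification is internally inconsistent."""
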