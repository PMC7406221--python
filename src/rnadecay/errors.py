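"""Exception hierarchy for the pipeline.

All pipeline-specific failures derive from :class:`RnaDecayError` so callers
(and the CLI) can distinguish bad inputs from genuine bugs.
"""


class RnaDecayError(Exception):
    """Base class for all pipeline errors."""


class FormatError(RnaDecayError):
    """Malformed input file (bad counts, duplicate ids, ...)."""


class ReferenceError_(RnaDecayError):
    """Annotation refers to a sequence or gene that does not exist."""


class ParameterError(RnaDecayError):
    """Invalid user-supplied parameter or configuration."""


class CalibrationError(RnaDecayError):
    """Spike-in calibration cannot proceed (too few points, zero sums)."""


class ContractError(RnaDecayError):
    """An internal precondition between pipeline stages was violated."""


class NoSignalError(RnaDecayError):
    """All abundances are zero; no decay fit is possible."""


class StructuralError(RnaDecayError):
    """Impossible RNA secondary-structure geometry was requested."""
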