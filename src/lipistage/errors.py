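"""Exception hierarchy.

All package errors derive from :class:`LipistageError` so callers (and the
CLI) can map failures to exit codes: validation/format problems exit 2,
degenerate models exit 3.
"""


class LipistageError(Exception):
    """Base class for all lipistage errors."""

    exit_code = 2


class ConfigurationError(LipistageError):
    """Invalid synthetic-cohort or run configuration; names the offending field."""


class FormatError(LipistageError):
    """Malformed input file (duplicate identifiers, unparseable cells)."""


class ValidationError(LipistageError):
    """Table content violates a domain invariant."""


class AlignmentError(LipistageError):
    """Feature and clinical tables share no samples."""


class ParameterError(LipistageError):
    """Out-of-range parameter passed to an operation."""


class MappingError(LipistageError):
    """Replicate map references an unknown sample."""


class CodingError(LipistageError):
    """Unrecognized categorical label during numeric coding."""


class AssemblyError(LipistageError):
    """Design-matrix assembly failed (e.g. an empty class for a scenario)."""


class SplitError(LipistageError):
    """Stratified split impossible (a class with fewer than 2 samples)."""


class InputError(LipistageError):
    """Invalid numeric input to a fitted model (wrong columns, non-finite)."""


class TrainingError(LipistageError):
    """Model training diverged (non-finite loss)."""

    exit_code = 3


class DegenerateModelError(LipistageError):
    """A model collapsed to an intercept-only predictor where that is fatal."""

    exit_code = 3
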