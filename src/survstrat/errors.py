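"""Exception taxonomy shared across the toolkit.

Every error raised on a user-facing code path derives from
:class:`SurvstratError` so callers can catch the package's failures with a
single ``except`` clause.
"""


class SurvstratError(Exception):
    """Base class for all survstrat errors."""


class DuplicateIdError(SurvstratError):
    """A feature or sample identifier occurs more than once."""


class ParseError(SurvstratError):
    """A cell of an input table could not be parsed; carries coordinates."""

    def __init__(self, message: str, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column


class ValidationError(SurvstratError):
    """An input value violates a documented invariant."""


class AlignmentError(SurvstratError):
    """Two per-sample structures do not share the required sample set."""


class EmptyCohortError(SurvstratError):
    """An operation received zero samples."""


class DegenerateGroupError(SurvstratError):
    """A grouping has an empty (or otherwise unusable) group."""


class NoContrastError(SurvstratError):
    """A binary indicator takes a single value; no contrast to estimate."""


class SeparationError(SurvstratError):
    """Monotone partial likelihood: the Cox estimate diverges.

    Carries the diagnostics gathered before divergence was declared.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UnderpoweredGroupError(SurvstratError):
    """A group is too small for the requested test."""


class EmptyAfterFilterError(SurvstratError):
    """A filter removed every feature."""


class NoValidCutoffError(SurvstratError):
    """No candidate cut-off satisfies the admissibility constraints."""


class ScanFailedError(SurvstratError):
    """Every admissible candidate failed to produce a model fit."""


class SelectionFailedError(SurvstratError):
    """Forward selection could not stratify any candidate subset."""


class UnstablePartitionError(SurvstratError):
    """Too many cross-validation folds violated scan preconditions."""


class CalibrationError(SurvstratError):
    """A simulation target (e.g. censoring fraction) is unattainable."""


class ConfigError(SurvstratError):
    """A pipeline configuration is invalid or incomplete."""


class EmptySignatureWarning(UserWarning):
    """A signature construction produced no members (non-fatal)."""
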