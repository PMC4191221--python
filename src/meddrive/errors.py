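"""Exception hierarchy for the meddrive package."""


class MedDriveError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(MedDriveError, ValueError):
    """An argument violates a documented precondition."""


class MalformedSessionError(MedDriveError):
    """A session log does not have the trial structure the protocol requires."""


class InsufficientDataError(MedDriveError):
    """Too few data points for the requested computation."""


class DegenerateDesignError(MedDriveError):
    """Regression design matrix has no variance (e.g. a single trial number)."""


class NoThresholdError(MedDriveError):
    """Staircase history contains no reversal; no threshold can be estimated."""


class NonConvergenceError(MedDriveError):
    """The staircase hit its trial cap without meeting the termination rule."""


class SchemaValidationError(MedDriveError):
    """A session record failed schema validation."""

    def __init__(self, message: str, fields: list[str] | None = None):
        super().__init__(message)
        self.fields = fields or []


class UnsupportedVersionError(MedDriveError):
    """A session record declares a schema version this build cannot read."""


class SessionParseError(MedDriveError):
    """A session file could not be parsed at all."""
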