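"""Exception hierarchy and warning categories.

The command-line layer maps each class to a distinct exit code so that
scripts driving the tool can tell a malformed file from a semantically
invalid scenario from an infeasible staffing question.
"""


class ChwPlanError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(ChwPlanError):
    """A scenario or fixture file could not be parsed as structured text."""


class SchemaError(ChwPlanError):
    """Parsed input does not match the documented schema.

    Carries the full list of field-level issues so every violation in a
    file is reported at once rather than one per run.
    """

    def __init__(self, message: str, issues: list[str] | None = None):
        self.issues = list(issues or [])
        if self.issues:
            message = message + "\n  - " + "\n  - ".join(self.issues)
        super().__init__(message)


class ConfigurationError(ChwPlanError):
    """Semantically invalid configuration.

    Examples: an intervention referencing a cadre that does not exist, a
    target keyed to a demographic group the profile does not define, or a
    what-if edit naming an unknown element.
    """


class InfeasibilityError(ChwPlanError):
    """The staffing question has no finite answer.

    Raised when a cadre carries positive service demand but its time
    policy leaves zero annual service hours per worker.
    """


class ConfigurationWarning(UserWarning):
    """Non-fatal configuration oddity (empty package, more cadres than
    the planning convention of six, mismatched profiles in a comparison,
    unrecognized file keys kept for forward compatibility)."""
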