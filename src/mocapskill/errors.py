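"""Exception hierarchy for mocapskill.

All package-specific failures derive from :class:`MocapSkillError` so callers
can catch the whole family with one clause.
"""


class MocapSkillError(Exception):
    """Base class for all mocapskill errors."""


class MalformedRecordingError(MocapSkillError):
    """A trajectory file or recording violates the recording invariants."""


class SchemaError(MocapSkillError):
    """A tabular input is missing required columns or contains duplicates."""


class DegenerateInputError(MocapSkillError):
    """Input is formally valid but statistically degenerate (e.g. zero variance)."""


class InsufficientDataError(MocapSkillError):
    """Too few frames or trials to compute the requested quantity."""


class IncompleteTrialError(MocapSkillError):
    """A trial record lacks a score needed for the requested computation."""


class ReconciliationError(MocapSkillError):
    """Trial identifiers in recordings and the score table do not match."""
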