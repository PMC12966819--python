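"""Exception hierarchy for tierstack.

All package-specific failures derive from :class:`TierstackError` so callers
can catch one base class at pipeline level while tests target the specific
condition.
"""


class TierstackError(Exception):
    """Base class for all tierstack errors."""


class InvalidSpecError(TierstackError, ValueError):
    """A cohort / scenario / grid specification violates its invariants."""


class AbsentYearError(TierstackError, KeyError):
    """A requested year index is not present in the cohort."""


class OrderingError(TierstackError, ValueError):
    """Train year does not precede the validation year."""


class DomainError(TierstackError, ValueError):
    """An input value lies outside the operation's domain."""


class ShapeError(TierstackError, ValueError):
    """Aligned inputs disagree in length or schema."""


class DegenerateTargetError(TierstackError, ValueError):
    """A binary fit was requested on single-class labels."""


class MissingDataError(TierstackError, ValueError):
    """Features contain missing values (complete-case analysis required)."""


class SchemaMismatchError(TierstackError, ValueError):
    """Scoring features do not match the training schema."""


class MissingTierError(TierstackError, ValueError):
    """A usage tier required for balancing is absent from the training data."""


class EmptyInputError(TierstackError, ValueError):
    """An operation requiring at least one element received none."""


class UnbalancedInputError(TierstackError, ValueError):
    """The meta-learner was asked to fit unbalanced tiers with balancing required."""


class UndefinedMetricError(TierstackError, ValueError):
    """A confusion-matrix metric is undefined (empty denominator)."""


class StageError(TierstackError, RuntimeError):
    """A pipeline stage failed; carries the stage tag."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
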