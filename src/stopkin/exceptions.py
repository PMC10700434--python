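"""Exception hierarchy for stopkin."""


class StopkinError(Exception):
    """Base class for all stopkin errors."""


class SchemaError(StopkinError):
    """A session file is missing mandatory columns or fields."""


class SessionValidationError(StopkinError):
    """A session violates a structural invariant (names the offending trial)."""


class GeometryError(StopkinError):
    """Trial geometry is inconsistent (e.g. cursor inside a target before go onset)."""


class InsufficientDataError(StopkinError):
    """Too few samples or trials to compute the requested quantity."""


class TrialCategoryError(StopkinError):
    """A trial does not belong to the category an estimator requires."""


class EstimationError(StopkinError):
    """A quantity is undefined for the given inputs (e.g. p_respond in {0, 1})."""
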