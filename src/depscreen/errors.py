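"""Exception hierarchy for cohort validation and screening."""


class DepscreenError(Exception):
    """Base class for all package errors."""


class CohortSchemaError(DepscreenError):
    """A cohort table is missing a required column or has a malformed header."""


class DuplicateMouseIdError(DepscreenError):
    """Two records in a cohort share a mouse_id."""


class BoundsError(DepscreenError):
    """A measure value lies outside the declared bounds of its MeasureSpec."""


class UnknownGroupError(DepscreenError):
    """A group label is not one of the recognized group names."""


class SingleClassError(DepscreenError):
    """ROC analysis requires at least one positive and one negative label."""


class MissingMeasureError(DepscreenError):
    """An animal lacks a value required by a scoring criterion."""


class MissingLatentError(DepscreenError):
    """Recovery evaluation requires latent susceptibility tags on all stressed animals."""
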