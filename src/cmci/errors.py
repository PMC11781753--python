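"""Exception hierarchy for the cmci package.

All package-specific failures derive from :class:`CmciError` so callers (and
the CLI) can distinguish data/analysis problems from programming errors.
"""


class CmciError(Exception):
    """Base class for all cmci errors."""


class ParseError(CmciError):
    """A recording or manifest file could not be parsed/validated."""


class ValidationError(CmciError):
    """An in-memory object violates its invariants."""


class InsufficientExtremaError(CmciError):
    """A series has too few extrema to build envelopes / continue sifting."""


class EmptyRetentionError(CmciError):
    """Mode truncation discarded every IMF."""


class StratificationError(CmciError):
    """A stratified split/fold plan cannot be built for these labels."""


class DegenerateModelError(CmciError):
    """Training data cannot support a classifier (e.g. single class)."""


class EvaluationError(CmciError):
    """ROC evaluation is impossible (e.g. single-class test set)."""


class InsufficientDataError(CmciError):
    """Too few observations for a statistical comparison."""
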