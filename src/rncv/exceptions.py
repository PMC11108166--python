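"""Exception hierarchy for rncv.

All errors raised by this package derive from :class:`RncvError` so callers
can catch package failures with a single except clause.  The subclasses map
onto the distinct failure modes of the evaluation machinery: malformed
generator specs, label bookkeeping problems, missing cells in tabular input,
fold plans that cannot satisfy stratification, training partitions that lost
a class, and AUC evaluations on single-class folds.
"""


class RncvError(Exception):
    """Base class for all rncv errors."""


class InvalidSpecError(RncvError, ValueError):
    """A generator or pipeline specification violates its invariants."""


class LabelArityError(RncvError, ValueError):
    """A label vector does not contain exactly two distinct classes."""


class MissingValueError(RncvError, ValueError):
    """Tabular input contains missing or unparseable cells."""


class StratificationError(RncvError, ValueError):
    """Stratified folds are infeasible: some class has fewer rows than folds."""


class DegenerateFoldError(RncvError, ValueError):
    """A training partition contains only one class; the model cannot be fit."""


class UndefinedAUCError(RncvError, ValueError):
    """AUC is undefined because one class is absent from the evaluation fold."""
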