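"""Exception hierarchy for sipscope.

Plain ``ValueError`` is raised for invalid arguments (bad numeric ranges,
degenerate spans); everything domain-specific derives from :class:`SipScopeError`
so callers can catch pipeline failures in one place.
"""


class SipScopeError(Exception):
    """Base class for all sipscope-specific errors."""


class DuplicateRecordError(SipScopeError):
    """Two records share a key that must be unique (e.g. gradient fraction)."""


class InsufficientDataError(SipScopeError):
    """Not enough observations to compute the requested quantity."""


class EmptyPoolError(SipScopeError):
    """A sequencing pool contains no RNA mass to sample reads from."""


class PoolSelectionError(SipScopeError):
    """No pool assignment satisfies the minimum-mass and disjointness rules."""

    def __init__(self, pool_label: str, message: str):
        self.pool_label = pool_label
        super().__init__(f"{pool_label}: {message}")


class MissingClassError(SipScopeError):
    """A read class required for the computation is absent from the library."""


class DivisionUndefinedError(SipScopeError):
    """An enrichment-factor ratio has a zero denominator and no pseudo-abundance."""


class IncompleteDesignError(SipScopeError):
    """The four-pool SIP design (12C/13C x heavy/light) is not complete."""


class DesignMixingError(SipScopeError):
    """Amplified and unamplified libraries were mixed in one analysis."""


class MissingLineageError(SipScopeError):
    """A requested parent clade or category does not occur in the lineages."""


class TableFormatError(SipScopeError):
    """A TSV file does not conform to the expected schema."""
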