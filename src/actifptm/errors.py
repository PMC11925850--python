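"""Exception hierarchy.

Every error raised by this package derives from :class:`ActifptmError`
so callers can catch the whole family with one clause.  The CLI maps the
subclasses onto distinct exit codes.
"""


class ActifptmError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(ActifptmError):
    """An input violates a structural invariant (shape, normalization,
    chain contiguity, probability bounds...)."""


class DialectError(ValidationError):
    """A file could not be matched to, or parsed under, a known dialect."""


class MissingComponentError(ActifptmError):
    """A score was requested that needs a component the bundle lacks
    (e.g. pTM without the binned error tensor)."""


class SingleChainError(ValidationError):
    """An interface score (ipTM, actifpTM, ...) was requested for a
    single-chain prediction, for which it is undefined."""


class NoInterfaceError(ActifptmError):
    """An interface-restricted quantity was requested but no residue
    pair qualifies as interface under the current contact call."""
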