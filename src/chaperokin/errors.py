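"""Exception hierarchy.

All package-specific failures derive from :class:`ChaperokinError` so callers
can catch one base class; the subclasses also derive from the matching builtin
(``ValueError`` / ``RuntimeError``) for idiomatic handling.
"""


class ChaperokinError(Exception):
    """Base class for all package errors."""


class ParameterError(ChaperokinError, ValueError):
    """A model parameter is out of its admissible range."""


class InputError(ChaperokinError, ValueError):
    """User-supplied data violates an input contract."""


class SchemaError(InputError):
    """A file does not match its documented column schema."""


class NumericalError(ChaperokinError, RuntimeError):
    """The integrator or optimizer failed; the message carries diagnostics."""


class NoTransitionError(ChaperokinError, ValueError):
    """A melt curve shows no resolvable folded-to-unfolded transition."""


class DegenerateProfileError(ChaperokinError, ValueError):
    """A rate-vs-concentration profile carries no information (all rates zero)."""
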