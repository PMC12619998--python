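"""Exception hierarchy.

Everything raised on bad user input derives from :class:`TomtomLiteError`
so callers (and the CLI) can catch one type. Subclasses also derive from
the closest builtin (``ValueError``) so untargeted ``except ValueError``
code keeps working.
"""


class TomtomLiteError(Exception):
    """Base class for all errors raised by this package."""


class MotifWidthError(TomtomLiteError, ValueError):
    """Motif has no columns, or a width constraint is violated."""


class NormalizationError(TomtomLiteError, ValueError):
    """A frequency-motif column does not sum to 1 within tolerance."""


class UnsupportedAlphabetError(TomtomLiteError, ValueError):
    """Operation requires a 4-letter complementable alphabet."""


class UnsupportedSemanticsError(TomtomLiteError, ValueError):
    """Operation defined for frequency motifs only (or vice versa)."""


class ShapeMismatchError(TomtomLiteError, ValueError):
    """Array shapes disagree with each other or with declared sizes."""


class MotifFormatError(TomtomLiteError, ValueError):
    """A motif file does not follow the expected text format."""


class DuplicateNameError(TomtomLiteError, ValueError):
    """Motif names must be unique within a set."""


class EmptyInputError(TomtomLiteError, ValueError):
    """An operation received an empty motif set / score grid."""
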