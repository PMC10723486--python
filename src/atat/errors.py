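"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`ATATError`
so callers can catch the package's failures with a single clause; the
common Python idioms (``ValueError`` for bad arguments) are preserved by
multiple inheritance.
"""


class ATATError(Exception):
    """Base class for all errors raised by this package."""


class InvalidArgumentError(ATATError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(ATATError, ValueError):
    """Input is structurally valid but degenerate (all-zero matrix,
    zero-variance channel, single-spot path, ...)."""


class FormatError(ATATError, ValueError):
    """An on-disk file does not follow the expected dialect, or files in a
    bundle do not reconcile with each other."""


class BoundsError(ATATError, ValueError):
    """A spot's tile footprint falls outside the slide image."""


class ContractError(ATATError, RuntimeError):
    """Two objects passed together do not belong together (spot-id
    mismatch, tile-statistics fingerprint mismatch, ...)."""


class NoPathError(ATATError, RuntimeError):
    """The two anchors lie in different connected components."""


class AnnotationError(ATATError, ValueError):
    """Boundary annotations are inconsistent with the traversed path."""


class UndefinedCorrelationError(ATATError, ValueError):
    """Rank correlation is undefined because an input is constant."""
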