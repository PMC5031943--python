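"""Exception hierarchy.

All errors raised by the package derive from :class:`UmvcueError` so that
callers can catch the package's failures without masking programming errors.
"""


class UmvcueError(Exception):
    """Base class for all package errors."""


class InputError(UmvcueError, ValueError):
    """Invalid user-supplied data (bad table, bad counts, bad matrix)."""


class EventViolationError(UmvcueError, ValueError):
    """The observed stage-1 estimates do not satisfy the selection event.

    The theory conditions on the *observed* ranking; silently reordering the
    candidates would change the estimand, so a violated event is an error.
    """


class InconsistentTruncationError(UmvcueError, RuntimeError):
    """A y-free ranking constraint is violated while building the truncation
    set — indicates the selection event was never checked on this data."""


class MassUnderflowError(UmvcueError, FloatingPointError):
    """The conditional probability of the truncation set underflowed even in
    scaled (erfcx-based) arithmetic; the estimate would be meaningless."""
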