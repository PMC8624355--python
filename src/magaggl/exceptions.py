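"""Exception types raised by the physical model layers."""


class MagagglError(Exception):
    """Base class for package errors."""


class ContactViolationError(MagagglError, ValueError):
    """Centre-to-centre distance smaller than the particle diameter."""


class BracketError(MagagglError, RuntimeError):
    """A bracketed root search found no sign change on the given interval."""


class NoSolutionError(MagagglError, RuntimeError):
    """The concentration equation has no root in the physical range."""


class CycleError(MagagglError, ValueError):
    """A field/magnetisation trajectory does not form a closed cycle."""


class TimestepError(MagagglError, ValueError):
    """The integrator timestep is too coarse for the precession frequency."""
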