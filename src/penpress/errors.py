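"""Exception hierarchy."""


class PenpressError(Exception):
    """Base class for package errors."""


class InvalidInputError(PenpressError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(PenpressError, ValueError):
    """Not enough observations to form the requested estimate."""


class FormatError(PenpressError, ValueError):
    """A file does not conform to the expected tabular/audio format."""


class StiffnessFailureError(PenpressError, RuntimeError):
    """The poro-elastic solver produced a non-physical state (porosity <= 0)."""
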