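"""Exception hierarchy for adipoflame."""


class AdipoflameError(Exception):
    """Base class for all adipoflame errors."""


class InvalidInputError(AdipoflameError, ValueError):
    """An argument is outside its valid domain (non-positive height, unknown gender, ...)."""


class InvalidParameterError(AdipoflameError, ValueError):
    """A model parameter violates its constraints (delta_ffm >= 1, negative rate, ...)."""


class InfeasibleSubjectError(AdipoflameError):
    """The anthropometric regression places the subject outside its validity range.

    Raised when the predicted fat mass is (near) zero or negative: such a
    subject has no fat reservoir and the volume-to-weight map degenerates.
    """
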