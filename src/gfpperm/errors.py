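"""Exception types raised by gfpperm."""


class GfppermError(Exception):
    """Base class for all gfpperm errors."""


class InvalidMontageError(GfppermError):
    """Raised when an operation requires at least two channels."""


class EmptyConditionError(GfppermError):
    """Raised when a requested condition has no trials."""


class IncompatibleDatasetsError(GfppermError):
    """Raised when multi-subject inputs disagree on montage or time axis."""


class ApproximationRangeError(GfppermError):
    """Raised when the delta-method expected-GFP radicand is negative.

    The offending radicand is stored on the ``radicand`` attribute so
    callers can inspect how far outside the approximation's range the
    moments fell.
    """

    def __init__(self, radicand: float):
        self.radicand = float(radicand)
        super().__init__(
            f"expected-GFP approximation out of range: radicand = {radicand!r} < 0"
        )


class ZeroNoiseError(GfppermError):
    """Raised when an SNR denominator (residual noise RMS) is zero."""
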