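"""Exception types shared across the package."""


class SpikeOscError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SpikeOscError, ValueError):
    """An argument violates a documented precondition."""


class SaturationError(SpikeOscError, ValueError):
    """The requested rate cannot be represented at the simulation resolution
    (per-bin spike probability would reach 1)."""


class InsufficientDataError(SpikeOscError, ValueError):
    """The spike train is too short/sparse for the requested operation."""


class DegenerateInputError(SpikeOscError, ValueError):
    """Input is formally valid but leads to a degenerate computation
    (e.g. dead-time budget exhausting the recording)."""


class DegenerateNoiseBandError(SpikeOscError, ArithmeticError):
    """The noise band has zero power variance, so SNR is undefined."""
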