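"""Exception hierarchy for wavesep.

All package errors derive from :class:`WavesepError` so callers can catch a
single base class at pipeline boundaries.
"""


class WavesepError(Exception):
    """Base class for all wavesep errors."""


class FormatError(WavesepError):
    """A waveform file is malformed (missing column, bad header, ...)."""


class SamplingError(WavesepError):
    """The time grid is non-uniform beyond tolerance or too short."""


class ConfigError(WavesepError):
    """A subject/phantom configuration value is invalid."""


class ParameterError(WavesepError):
    """A physical parameter passed to an operation is out of range."""


class FlatFlowError(WavesepError):
    """Velocity never rises above the noise floor; no ejection detected."""


class NoValveClosureError(WavesepError):
    """No end-systolic landmark could be located before the beat end."""


class EmptySetError(WavesepError):
    """An operation that needs at least one beat received none."""


class FitError(WavesepError):
    """The diastolic monoexponential fit failed to converge or is degenerate.

    Carries residual diagnostics in ``diagnostics`` when available.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateSignalError(WavesepError):
    """A signal required for a ratio/normalisation is identically degenerate."""
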