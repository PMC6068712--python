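"""Exception hierarchy for ecgkit.

Every error raised by the library derives from :class:`EcgKitError`, so
callers embedding the cascade can catch one type at the pipeline boundary.
"""


class EcgKitError(Exception):
    """Base class for all ecgkit errors."""


class FormatError(EcgKitError):
    """Malformed or unsupported input file (bad CSV timestamps, unknown WFDB format)."""


class ConfigurationError(EcgKitError):
    """Invalid parameter combination (e.g. band edge above Nyquist)."""


class DegenerateSignalError(EcgKitError):
    """Signal is constant or all-zero where variation is required."""


class TooShortError(EcgKitError):
    """Record shorter than one analysis window."""


class InsufficientBeatsError(EcgKitError):
    """Too few beats / RR intervals for a beat-interval statistic."""
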