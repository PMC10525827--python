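"""Exception hierarchy shared across the pipeline stages."""


class EmbryokinError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EmbryokinError):
    """A pose-track or annotation file does not follow its dialect."""


class TrackValidationError(EmbryokinError):
    """A pose track violates an invariant (e.g. likelihood outside [0, 1])."""


class SchemeError(EmbryokinError):
    """A body-part scheme is inconsistent or cannot be bound to a track."""


class DesignError(EmbryokinError):
    """A trial design is invalid or does not fit inside the recording."""


class ParameterError(EmbryokinError):
    """An analysis parameter is outside its allowed range."""


class DegenerateDesignError(EmbryokinError):
    """A statistical model cannot be identified from the given data."""
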