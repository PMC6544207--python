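"""Exception hierarchy shared across the toolkit."""


class OculofatigueError(Exception):
    """Base class for all toolkit errors."""


class FormatError(OculofatigueError):
    """A file does not match the documented format (e.g. missing column)."""


class IntegrityError(OculofatigueError):
    """Data violates an invariant (non-monotone time, overlapping events...)."""


class ValidationError(OculofatigueError):
    """A value is outside its documented range."""


class ConfigurationError(OculofatigueError):
    """A configuration value is unusable (e.g. non-positive viewing distance)."""


class SignalError(OculofatigueError):
    """A signal is too short or too degenerate to process."""


class ModeError(OculofatigueError):
    """An operation was invoked in the wrong biofeedback mode."""
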