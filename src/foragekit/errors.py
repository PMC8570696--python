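"""Exception hierarchy shared across the package."""


class ForagekitError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ForagekitError, ValueError):
    """A simulation or analysis parameter is invalid; the message names the field."""


class ScheduleError(ForagekitError, ValueError):
    """A light-pulse schedule is malformed (overlapping or out-of-range pulses)."""


class SchemaError(ForagekitError, ValueError):
    """An on-disk table violates the documented schema; the message names the row."""
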