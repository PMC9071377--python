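"""Exception hierarchy shared across bhlhkit modules."""


class BhlhkitError(Exception):
    """Base class for all bhlhkit errors."""


class ConfigurationError(BhlhkitError):
    """A configuration value is invalid; the message names the field."""


class InputError(BhlhkitError):
    """An input object violates a precondition."""


class StateError(BhlhkitError):
    """An operation was applied to an object in the wrong state."""
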