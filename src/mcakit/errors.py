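"""Exception hierarchy."""


class McaKitError(Exception):
    """Base class for package errors."""


class ConfigurationError(McaKitError):
    """Invalid configuration (distribution spec, thresholds, resample counts)."""


class InputError(McaKitError):
    """Invalid input data (overlapping events, unsorted sites, bad coordinates)."""
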