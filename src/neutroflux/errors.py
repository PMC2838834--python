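"""Exception hierarchy shared across the pipeline."""


class NeutrofluxError(Exception):
    """Base class for all package errors."""


class FormatError(NeutrofluxError):
    """A file does not conform to its expected on-disk layout."""


class IntegrityError(NeutrofluxError):
    """Parsed data violates a structural invariant."""


class ConfigError(NeutrofluxError):
    """An option or configuration value is out of its allowed domain."""
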