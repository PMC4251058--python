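"""Exception hierarchy shared across the package."""


class ClonaltrackError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ClonaltrackError):
    """Invalid configuration: unknown dialect, impossible consensus rule, bad manifest."""


class VcfParseError(ClonaltrackError):
    """A VCF record could not be interpreted under the requested dialect."""


class ValidationError(ClonaltrackError):
    """Input data violates a structural contract (e.g. overlapping CN segments)."""


class DomainError(ClonaltrackError):
    """A computation was requested outside its mathematical domain."""
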