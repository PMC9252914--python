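"""Exception hierarchy shared by all clonevo modules.

Exit-code mapping used by the CLI: ValidationError / FormatError /
IntegrityError -> 1, ConfigurationError -> 2.
"""


class ClonevoError(Exception):
    """Base class for all package errors."""


class ValidationError(ClonevoError):
    """Input values violate a documented invariant (bad counts, thresholds...)."""


class FormatError(ClonevoError):
    """A file could not be parsed under the declared dialect."""


class IntegrityError(ClonevoError):
    """Cross-input inconsistency (reference mismatch, region-id mismatch...)."""


class ConfigurationError(ClonevoError):
    """Required inputs or settings are missing for the requested operation."""
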