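"""Exception types shared across the package."""


class StrainPulseError(Exception):
    """Base class for all package errors."""


class DomainError(StrainPulseError, ValueError):
    """A physical quantity is outside its valid domain (e.g. plate contact)."""


class ConfigurationError(StrainPulseError, ValueError):
    """A configuration is internally inconsistent or infeasible."""
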