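"""Exception hierarchy shared by all tomobreast modules."""


class TomobreastError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TomobreastError):
    """A structured configuration violated an invariant; names the field."""


class DomainError(TomobreastError, ValueError):
    """An argument fell outside its mathematical/physical domain."""


class LookupErrorTB(TomobreastError, KeyError):
    """An unknown material or label was requested."""
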