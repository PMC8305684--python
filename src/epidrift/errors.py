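"""Exception hierarchy; CLI maps these onto distinct exit codes."""


class EpidriftError(Exception):
    """Base class for all package errors."""


class ArgumentError(EpidriftError, ValueError):
    """A function argument violates its documented precondition."""


class InputError(EpidriftError):
    """Malformed or inconsistent input data (files, tables, coordinates)."""


class ConfigurationError(EpidriftError):
    """Invalid run configuration (overlapping rules, missing sample classes...)."""
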