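"""Exception types shared across the package."""


class EchocountError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EchocountError, ValueError):
    """A parameter is outside its valid domain or a spec is infeasible."""


class UndefinedStatisticError(EchocountError, ZeroDivisionError):
    """A statistic is requested whose denominator is empty (no fish, no coverage)."""


class InputError(EchocountError, ValueError):
    """An input array or file violates a structural precondition."""
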