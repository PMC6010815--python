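"""Exception types shared across the package."""


class IsobarrierError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(IsobarrierError, ValueError):
    """An input violates a documented precondition (bad interval, label, schema...)."""


class UndefinedRIError(IsobarrierError, ValueError):
    """An isolation index is requested where it is mathematically undefined.

    Raised when both the conspecific and heterospecific success measures are
    zero: with no mating events observed in either class there is no
    information about isolation, and returning 0 would silently assert
    "no isolation".
    """
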