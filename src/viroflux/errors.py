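"""Exception hierarchy shared across the pipeline stages."""


class VirofluxError(Exception):
    """Base class for all errors raised by viroflux."""


class ParameterError(VirofluxError, ValueError):
    """An argument or scenario field is outside its admissible range."""


class DataError(VirofluxError, ValueError):
    """Input data violate a structural requirement (shape, sign, coverage)."""


class UndefinedStatisticError(VirofluxError, ValueError):
    """A statistic is undefined for the given input (e.g. constant vector)."""
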