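"""Exception hierarchy.

All package errors derive from :class:`ZsDecodeError` so callers can catch
one base class; the subclasses distinguish bad user input, bad configuration,
and numerical breakdown during inference.
"""


class ZsDecodeError(Exception):
    """Base class for all errors raised by zsdecode."""


class DataError(ZsDecodeError, ValueError):
    """Invalid input data: wrong shapes, non-finite entries, bad manifests."""


class ConfigError(ZsDecodeError, ValueError):
    """Inconsistent or out-of-range model/run configuration."""


class NumericalError(ZsDecodeError, ArithmeticError):
    """Non-finite intermediate or failed factorization during inference."""
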