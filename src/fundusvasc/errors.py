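"""Exception hierarchy shared across the pipeline."""


class FundusvascError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(FundusvascError, ValueError):
    """A parameter or input violates a stated precondition."""


class FormatError(FundusvascError, ValueError):
    """An input file is structurally unusable (wrong size, zero pixels, ...)."""


class DetectionError(FundusvascError, RuntimeError):
    """Automatic optic-disc detection failed; supply manual coordinates."""


class DegenerateDataError(FundusvascError, ValueError):
    """Data admit no test statistic (e.g. all paired differences are zero)."""
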