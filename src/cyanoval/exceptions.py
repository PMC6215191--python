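"""Exception hierarchy for cyanoval.

Every error raised on purpose by the library derives from
:class:`CyanovalError`, so callers (and the CLI) can catch one type.
"""


class CyanovalError(Exception):
    """Base class for all cyanoval errors."""


class ModelError(CyanovalError, ValueError):
    """An analyte response model violates its invariants (e.g. slope <= 0)."""


class DesignError(CyanovalError, ValueError):
    """An experimental design is unusable (too few blanks, unbalanced days...)."""


class FitError(CyanovalError, ValueError):
    """A calibration fit cannot be performed on the supplied data."""


class InversionError(CyanovalError, ValueError):
    """A calibration curve cannot be inverted (zero slope)."""


class ConfigError(CyanovalError, ValueError):
    """A configuration file or mapping is malformed or inconsistent."""


class ParseError(CyanovalError, ValueError):
    """A measurement table could not be parsed.

    ``line`` is the 1-based line number in the file (header = line 1)
    when the problem is attributable to a single row, else ``None``.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
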