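"""Exception types raised by rrseg."""


class RRSegError(ValueError):
    """Base class for rrseg errors."""


class RRParseError(RRSegError):
    """A text RR file contained a line that does not parse."""

    def __init__(self, path, lineno, line):
        self.path = str(path)
        self.lineno = lineno
        self.line = line
        super().__init__(f"{path}: line {lineno}: cannot parse {line!r} as a positive number")


class EmptyInputError(RRSegError):
    """An operation received an empty series or file."""


class DegenerateInputError(RRSegError):
    """Input is formally valid but unusable (e.g. every beat rejected)."""


class InsufficientDataError(RRSegError):
    """Too few observations for the requested fit or statistic."""


class UndefinedStatisticError(RRSegError):
    """The statistic is undefined for this input (e.g. %mu50 of one segment)."""


class CurveFitError(RRSegError):
    """A nonlinear fit failed to converge; carries residuals when known."""

    def __init__(self, message, residuals=None):
        self.residuals = residuals
        super().__init__(message)
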