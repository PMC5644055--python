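"""Exception hierarchy shared across the package."""


class CalciumPeaksError(Exception):
    """Base class for all errors raised by calciumpeaks."""


class FormatError(CalciumPeaksError):
    """The input file is readable but does not match a supported CSV dialect."""


class EmptyDataError(CalciumPeaksError):
    """No complete ROI survived incomplete-data filtering."""


class DegenerateTrendError(CalciumPeaksError):
    """A smoothed trend is zero or negative where the trace would be divided by it."""


class ParameterError(CalciumPeaksError, ValueError):
    """A user-supplied parameter is outside its valid range."""
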