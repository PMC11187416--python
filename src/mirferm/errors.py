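"""Exception hierarchy.

All mirferm errors derive from :class:`MirfermError` so callers can catch the
package's failures with a single except clause; each subclass maps to one
guarded precondition in the public API.
"""


class MirfermError(Exception):
    """Base class for all mirferm errors."""


class GridMismatchError(MirfermError, ValueError):
    """Two spectra do not share an identical wavenumber grid."""


class WindowRangeError(MirfermError, ValueError):
    """A band window lies (partly) outside the spectrum's wavenumber range."""


class SingularDesignError(MirfermError, ValueError):
    """Regression design is singular (e.g. all absorbances identical)."""


class InsufficientDataError(MirfermError, ValueError):
    """Too few observations for the requested fit or statistic."""


class DivisionGuardError(MirfermError, ZeroDivisionError):
    """Ratio estimator hit a zero absorbance."""


class UndefinedR2Error(MirfermError, ValueError):
    """R^2 undefined because the reference series is constant."""


class SpectrumParseError(MirfermError, ValueError):
    """Malformed spectrum file; message carries the offending line number."""


class ConfigError(MirfermError, ValueError):
    """Run configuration failed schema validation."""
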