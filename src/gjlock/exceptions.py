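"""Exception hierarchy for gjlock.

All gjlock errors derive from :class:`GjLockError` so callers can catch the
package's failures with a single ``except`` clause; each concrete class also
derives from ``ValueError`` so plain-Python callers behave sensibly.
"""


class GjLockError(Exception):
    """Base class for all gjlock errors."""


class InvalidParameterError(GjLockError, ValueError):
    """A parameter violates its documented precondition."""


class AliasingError(GjLockError, ValueError):
    """Carrier frequency at or above the Nyquist frequency of the sampling."""


class InsufficientDataError(GjLockError, ValueError):
    """The analysis window does not contain the requested number of cycles."""


class UnitError(GjLockError, ValueError):
    """An operation received data in the wrong units (e.g. uncalibrated map)."""


class DegenerateFitError(GjLockError, ValueError):
    """A fit cannot be performed (zero spread, zero variance, empty input)."""


class NormalizationError(GjLockError, ValueError):
    """Relative-amplitude normalisation is unreliable (A1 at/below noise)."""


class ConfigError(GjLockError, ValueError):
    """A run configuration failed schema validation."""
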