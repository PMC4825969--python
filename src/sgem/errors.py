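"""Exception hierarchy.

All errors raised by the package derive from :class:`SgemError`, so callers
can catch one base class. The subclasses mirror the distinct failure modes of
the simulator: bad simulation protocols, bad model parameters, malformed
inputs, violated process invariants, out-of-range queries, and calibration
failures.
"""


class SgemError(Exception):
    """Base class for all errors raised by sgem."""


class InvalidProtocolError(SgemError, ValueError):
    """A simulation protocol setting (horizon, step, ensemble size) is invalid."""


class UnsupportedParameterError(SgemError, ValueError):
    """A model parameter lies outside the supported domain (e.g. non-integer beta)."""


class InvalidInputError(SgemError, ValueError):
    """An input object is structurally invalid (empty trajectory, bad CSV row)."""


class InvariantViolationError(SgemError, ValueError):
    """An object violates a process invariant (e.g. an increasing residual curve)."""


class RangeError(SgemError, ValueError):
    """A query time or event lies outside the simulated grid."""


class CalibrationError(SgemError, RuntimeError):
    """Bisection failed to bracket or reach the requested Monte-Carlo median."""


class ProfileParseError(InvalidInputError):
    """A profile CSV failed validation; message names the offending line."""
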