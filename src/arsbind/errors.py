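"""Exception hierarchy for arsbind.

Invalid scalar arguments (negative concentrations, zero masses, unknown model
tags) raise plain :class:`ValueError`; the classes here mark failures of data
sufficiency, numerical fitting, or file parsing so callers can distinguish
"your numbers are nonsense" from "this dataset cannot support the analysis".
"""

from __future__ import annotations


class ArsBindError(Exception):
    """Base class for arsbind analysis errors."""


class InsufficientDataError(ArsBindError):
    """Too few usable points remain after exclusions to run an analysis."""


class FitFailureError(ArsBindError):
    """A regression produced a degenerate or unphysical result."""


class NoLinearSegmentError(ArsBindError):
    """No contiguous run of points met the linearity requirement.

    ``best`` carries the diagnostics of the best-scoring (rejected) window:
    a ``(start, stop, r_squared)`` tuple, or ``None`` when nothing could be
    fitted at all.
    """

    def __init__(self, message: str, best: tuple[int, int, float] | None = None):
        super().__init__(message)
        self.best = best


class AffinityUndefinedError(ArsBindError):
    """Scatchard intercept is non-positive, so K_A = slope/intercept is undefined.

    The partial fit (slope, intercept, R^2) is attached as ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class EquilibriumError(ArsBindError):
    """An equilibrium solver failed to locate a physical root."""


class ParseError(ArsBindError):
    """A delimited input table violated its schema; message names the cell."""


class ConfigError(ArsBindError):
    """A pipeline configuration is invalid or incomplete."""
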