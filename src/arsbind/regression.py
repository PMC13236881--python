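"""Shared ordinary-least-squares line fit and linear-segment selection.

Every estimator in this package is, by design, a straight-line fit of a
linearized model; the helpers here provide the fit with its full parameter
covariance (for delta-method error propagation) and the contiguous-segment
selector used to restrict fits to the linear regime of a plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitFailureError, NoLinearSegmentError


@dataclass(frozen=True)
class LineFit:
    """y = slope*x + intercept with OLS diagnostics.

    ``var_slope``, ``var_intercept`` and ``cov_slope_intercept`` come from the
    usual unbiased residual-variance estimate (zero when n == 2).
    """

    slope: float
    intercept: float
    r_squared: float
    n: int
    var_slope: float
    var_intercept: float
    cov_slope_intercept: float

    @property
    def slope_sd(self) -> float:
        return float(np.sqrt(self.var_slope))

    @property
    def intercept_sd(self) -> float:
        return float(np.sqrt(self.var_intercept))


def ols_line(x, y) -> LineFit:
    """Fit y on x by ordinary least squares; raise on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional arrays of equal length")
    n = len(x)
    if n < 2:
        raise FitFailureError(f"need at least 2 points for a line fit, got {n}")
    xbar = x.mean()
    ybar = y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0.0:
        raise FitFailureError("all x values identical: slope is undefined")
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    if ss_tot > 0:
        r_squared = 1.0 - ss_res / ss_tot
    else:
        # Horizontal data: perfect fit iff residuals vanish.
        r_squared = 1.0 if ss_res <= 1e-300 else 0.0
    sigma2 = ss_res / (n - 2) if n > 2 else 0.0
    var_slope = sigma2 / sxx
    var_intercept = sigma2 * (1.0 / n + xbar**2 / sxx)
    cov_si = -xbar * sigma2 / sxx
    return LineFit(
        slope=slope,
        intercept=intercept,
        r_squared=max(0.0, min(1.0, r_squared)),
        n=n,
        var_slope=var_slope,
        var_intercept=var_intercept,
        cov_slope_intercept=cov_si,
    )


def select_linear_segment(x, y, min_len: int = 4, r2_min: float = 0.99) -> tuple[int, int]:
    """Find the linear regime of a plot as a half-open index range ``(start, stop)``.

    Exhaustively scores every contiguous window of at least ``min_len``
    points and returns the longest one whose OLS R^2 meets ``r2_min``; ties
    are broken by higher R^2, then by lower starting index.  The full range
    is returned whenever the whole set qualifies (it is the longest window).

    Raises
    ------
    NoLinearSegmentError
        If no window qualifies; the error carries the best rejected window's
        ``(start, stop, r_squared)`` diagnostics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    if n < min_len:
        raise NoLinearSegmentError(f"need at least {min_len} points, got {n}")
    best_key = None
    best_range = None
    best_diag = None  # best window regardless of threshold, for diagnostics
    for i in range(n - min_len + 1):
        for j in range(i + min_len, n + 1):
            if np.all(y[i:j] == y[i]):
                # a flat window (e.g. a saturation plateau) carries no
                # linear-regime information; never a candidate
                continue
            try:
                r2 = ols_line(x[i:j], y[i:j]).r_squared
            except FitFailureError:
                continue
            if best_diag is None or r2 > best_diag[2]:
                best_diag = (i, j, r2)
            if r2 >= r2_min:
                key = (j - i, r2, -i)
                if best_key is None or key > best_key:
                    best_key = key
                    best_range = (i, j)
    if best_range is None:
        raise NoLinearSegmentError(
            f"no contiguous run of >= {min_len} points reached R^2 >= {r2_min}"
            + (f"; best window {best_diag[0]}:{best_diag[1]} had R^2 = {best_diag[2]:.4f}"
               if best_diag else ""),
            best=best_diag,
        )
    return best_range
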