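"""Scatchard analysis of equilibrium isotherms on particle-immobilized receptors.

For a receptor with n independent, identical sites per particle at particle
molarity [S]_t, the 1:1 binding equilibrium

    K_A = [M]_b / ([M]_f ([S]_t n - [M]_b))

linearizes, with the per-particle occupancy μ = [M]_b/[S]_t, to

    [M]_f / μ = K_D / n + [M]_f / n .

The occupancy is carried in units of 1e7 per-particle sites (μ_scaled =
μ/1e7), so that for site multiplicities of order 1e7 the regression
y = [M]_f/μ_scaled vs x = [M]_f has a slope of order one and

    n = 1e7 / slope          (sites per particle)
    K_A = slope / intercept  (μM^-1, numerically the 1e6 M^-1 display value)
    K_D = intercept / slope  (μM).

Delta-method standard errors for K_A and n are propagated from the regression
covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import IsothermDataset
from .errors import AffinityUndefinedError, InsufficientDataError
from .regression import LineFit, ols_line, select_linear_segment

#: Scale of the per-particle occupancy coordinate: μ is expressed in units of
#: 1e7 sites so Table-style slopes are order one.
MU_SCALE = 1.0e7


@dataclass(frozen=True)
class ScatchardPoint:
    """One transformed isotherm point: x = free ligand, y = free/occupancy."""

    m_free: float
    mu_scaled: float  # occupancy / 1e7
    y: float  # m_free / mu_scaled, μM


@dataclass(frozen=True)
class ScatchardFit:
    """Scatchard regression with derived binding constants.

    ``ka`` is in μM^-1, numerically identical to the conventional
    "x 1e6 M^-1" display value; ``n_e7`` is the per-particle site number in
    units of 1e7.  ``segment`` is the half-open index range of the points
    used.  ``ka_sd``/``n_sd`` are delta-method standard errors on the same
    scales.
    """

    slope: float
    intercept: float
    r_squared: float
    ka: float
    kd: float
    n_e7: float
    segment: tuple[int, int]
    ka_sd: float
    n_sd: float
    n_points: int

    @property
    def ka_e6_per_M(self) -> float:
        """K_A in units of 1e6 M^-1 (numerically equal to μM^-1)."""
        return self.ka

    @property
    def n_sites(self) -> float:
        """Sites per particle (n_e7 x 1e7)."""
        return self.n_e7 * MU_SCALE

    @property
    def equation(self) -> str:
        return f"y = {self.slope:.4f}x + {self.intercept:.4f}"


def affinity_from_line(slope: float, intercept: float) -> tuple[float, float]:
    """K_A (1e6 M^-1) and n (1e7 sites/particle) from a Scatchard line.

    The slope/intercept are those of the scaled regression
    y = [M]_f/(μ/1e7) on x = [M]_f with x in μM.  This is the formula pair
    applied to published regression equations when re-deriving tabulated
    constants.
    """
    if not slope > 0:
        raise ValueError(f"Scatchard slope must be positive, got {slope}")
    if not intercept > 0:
        raise AffinityUndefinedError(
            f"non-positive intercept {intercept}: K_A = slope/intercept undefined"
        )
    return slope / intercept, 1.0 / slope


def scatchard_transform(ds: IsothermDataset) -> list[ScatchardPoint]:
    """Transform isotherm points to Scatchard coordinates.

    Points with zero bound ligand carry no occupancy information and are
    skipped with a warning; if every point is skipped an
    :class:`InsufficientDataError` is raised.
    """
    st = ds.suspension.molar_conc
    if not st > 0:
        raise ValueError("suspension molar concentration must be positive")
    points: list[ScatchardPoint] = []
    skipped = 0
    for total, free, bound in zip(ds.total, ds.free, ds.bound):
        if bound <= 0:
            skipped += 1
            continue
        mu_scaled = bound / st / MU_SCALE
        points.append(ScatchardPoint(m_free=float(free), mu_scaled=float(mu_scaled),
                                     y=float(free / mu_scaled)))
    if skipped:
        warnings.warn(f"skipped {skipped} zero-bound point(s) in Scatchard transform",
                      stacklevel=2)
    if not points:
        raise InsufficientDataError("all points have zero bound ligand")
    return points


def scatchard_fit(points: list[ScatchardPoint],
                  segment: tuple[int, int] | None = None) -> ScatchardFit:
    """OLS Scatchard regression over ``segment`` (default: all points).

    Raises :class:`AffinityUndefinedError` (carrying the raw line fit as
    diagnostics) when the intercept is non-positive, and
    :class:`InsufficientDataError` below 3 points.
    """
    if segment is None:
        segment = (0, len(points))
    start, stop = segment
    pts = points[start:stop]
    if len(pts) < 3:
        raise InsufficientDataError(f"segment has {len(pts)} points; need >= 3")
    x = np.array([p.m_free for p in pts])
    y = np.array([p.y for p in pts])
    line = ols_line(x, y)
    if not line.slope > 0:
        raise AffinityUndefinedError(
            f"non-positive Scatchard slope {line.slope:.4g}", diagnostics=line
        )
    if not line.intercept > 0:
        raise AffinityUndefinedError(
            f"non-positive Scatchard intercept {line.intercept:.4g} "
            f"(slope {line.slope:.4g}, R^2 {line.r_squared:.4f})",
            diagnostics=line,
        )
    ka, n_e7 = affinity_from_line(line.slope, line.intercept)
    ka_sd = _delta_sd_ratio(line)
    n_sd = line.slope_sd / line.slope**2  # n_e7 = 1/slope
    return ScatchardFit(
        slope=line.slope,
        intercept=line.intercept,
        r_squared=line.r_squared,
        ka=ka,
        kd=line.intercept / line.slope,
        n_e7=n_e7,
        segment=(start, stop),
        ka_sd=ka_sd,
        n_sd=n_sd,
        n_points=len(pts),
    )


def _delta_sd_ratio(line: LineFit) -> float:
    """Delta-method SD of slope/intercept from the OLS covariance."""
    s, i = line.slope, line.intercept
    g = np.array([1.0 / i, -s / i**2])
    cov = np.array([[line.var_slope, line.cov_slope_intercept],
                    [line.cov_slope_intercept, line.var_intercept]])
    var = float(g @ cov @ g)
    return float(np.sqrt(max(var, 0.0)))


def affinity_from_isotherm(
    ds: IsothermDataset,
    min_len: int = 4,
    r2_min: float = 0.99,
    blank: IsothermDataset | None = None,
) -> ScatchardFit:
    """Full pipeline: (blank-correct,) average replicates, transform, select, fit.

    ``blank`` optionally supplies a bare-particle dataset measured at the same
    total-ligand levels; its bound amounts are subtracted point-wise before
    the transform (off by default — control preparations are normally fitted
    separately).
    """
    if blank is not None:
        ds = blank_corrected(ds, blank)
    ds = ds.averaged()
    points = scatchard_transform(ds)
    x = np.array([p.m_free for p in points])
    y = np.array([p.y for p in points])
    segment = select_linear_segment(x, y, min_len=min_len, r2_min=r2_min)
    return scatchard_fit(points, segment)


def blank_corrected(ds: IsothermDataset, blank: IsothermDataset) -> IsothermDataset:
    """Subtract a blank's bound amounts, matched on total-ligand levels."""
    ds_avg = ds.averaged()
    blank_avg = blank.averaged()
    blank_map = {t: b for t, b in zip(blank_avg.total, blank_avg.bound)}
    missing = [t for t in ds_avg.total if t not in blank_map]
    if missing:
        raise ValueError(f"blank dataset lacks total-ligand levels {missing}")
    corrected = np.array([max(b - blank_map[t], 0.0)
                          for t, b in zip(ds_avg.total, ds_avg.bound)])
    return IsothermDataset(
        total=ds_avg.total,
        free=ds_avg.total - corrected,
        bound=corrected,
        suspension=ds.suspension,
        ligand=ds.ligand,
        label=f"{ds.label} (blank-corrected)",
        params=dict(ds.params),
    )
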