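"""Competitive immobilized-vs-free affinity inference.

An immobilized receptor R (sites n[S], dissociation constant K_D1) and a free
protein P (K_D2) compete for the same ligand.  At equilibrium

    [R]_f/[R]_b = ([P]_f/[P]_b) * (K_D1/K_D2),

so a straight line of [R]_f/[R]_b against [P]_f/[P]_b has slope K_D1/K_D2 and
passes through the origin.  Closing the mass balances from the single
measured quantity (ligand on the solid phase, [R]_b) requires neglecting free
ligand — justified when both binders are strong and the ligand is not in
excess; the companion exact-equilibrium solver quantifies exactly how much
that closure costs.

The free protein's association constant follows from the immobilized
reference: K_A,free = (K_D1/K_D2) * K_A,immobilized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datasets import CompetitiveDataset
from .errors import InsufficientDataError
from .regression import ols_line
from .simulate import CompetitiveParams, solve_competitive_equilibrium

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MassBalancePoint:
    """One competition point after mass-balance closure.

    ``x`` = [P]_f/[P]_b and ``y`` = [R]_f/[R]_b are NaN when the point was
    excluded; ``reason`` records why.
    """

    as_total: float
    r_bound: float
    x: float
    y: float
    included: bool
    reason: str | None = None


@dataclass(frozen=True)
class CompetitiveFit:
    """Fitted affinity ratio K_D1/K_D2 with regression diagnostics.

    The intercept is retained as a diagnostic — the model implies zero — and
    reported rather than forced.
    """

    ratio: float
    intercept: float
    r_squared: float
    n_points_used: int
    points: tuple[MassBalancePoint, ...]


def competitive_mass_balance(ds: CompetitiveDataset) -> list[MassBalancePoint]:
    """Close the mass balances for every point, flagging unusable ones.

    Free ligand is set to zero (the strong-binding closure), so
    [P]_b = total - [R]_b, [R]_f = R_total - [R]_b, [P]_f = P_total - [P]_b.
    Points where any pool is non-positive are excluded with a reason; if all
    points are excluded an :class:`InsufficientDataError` is raised.
    """
    points: list[MassBalancePoint] = []
    for as_total, r_b in zip(ds.as_total, ds.r_bound):
        reason = None
        if as_total <= 0:
            reason = "no ligand"
        elif r_b <= 0:
            reason = "no solid-phase binding"
        else:
            p_b = as_total - r_b
            r_f = ds.r_total - r_b
            if p_b <= 0:
                reason = "competitor bound nothing (P_b <= 0)"
            elif r_f <= 0:
                reason = "immobilized sites saturated (R_f <= 0)"
            else:
                p_f = ds.p_total - p_b
                if p_f <= 0:
                    reason = "competitor sites saturated (P_f <= 0)"
        if reason is None:
            points.append(MassBalancePoint(
                as_total=float(as_total), r_bound=float(r_b),
                x=float(p_f / p_b), y=float(r_f / r_b), included=True))
        else:
            logger.info("competition point (total=%.4g) excluded: %s", as_total, reason)
            points.append(MassBalancePoint(
                as_total=float(as_total), r_bound=float(r_b),
                x=float("nan"), y=float("nan"), included=False, reason=reason))
    if not any(p.included for p in points):
        raise InsufficientDataError("every competition point was excluded")
    return points


def fit_affinity_ratio(points: list[MassBalancePoint]) -> CompetitiveFit:
    """OLS of [R]_f/[R]_b on [P]_f/[P]_b over the included points.

    The slope is the affinity ratio K_D1/K_D2.  Requires >= 3 usable points;
    identical x values raise :class:`~arsbind.errors.FitFailureError`.
    """
    used = [p for p in points if p.included]
    if len(used) < 3:
        raise InsufficientDataError(f"need >= 3 usable points, have {len(used)}")
    x = np.array([p.x for p in used])
    y = np.array([p.y for p in used])
    line = ols_line(x, y)
    if abs(line.intercept) > 0.05 * max(1.0, float(np.max(np.abs(y)))):
        logger.warning("competitive fit intercept %.4g deviates from the model's 0",
                       line.intercept)
    return CompetitiveFit(
        ratio=line.slope,
        intercept=line.intercept,
        r_squared=line.r_squared,
        n_points_used=len(used),
        points=tuple(points),
    )


@dataclass(frozen=True)
class FreeAffinityResult:
    """Free-protein affinity derived from the immobilized reference."""

    ka_free: float  # same units as the reference K_A
    ka_immobilized: float
    ratio: float
    deviation_pct: float  # 100 * |ka_free - ka_immobilized| / ka_free


def free_affinity(fit: CompetitiveFit | float, ka_immobilized: float) -> FreeAffinityResult:
    """Derive the free protein's K_A from the fitted ratio and the reference K_A.

    K_A,free = ratio x K_A,immobilized, since ratio = K_D1/K_D2 =
    K_A,P/K_A,R.  Also reports the relative deviation between the two
    affinities — the immobilization-effect metric.
    """
    ratio = fit.ratio if isinstance(fit, CompetitiveFit) else float(fit)
    if not ratio > 0:
        raise ValueError(f"affinity ratio must be positive, got {ratio}")
    if not ka_immobilized > 0:
        raise ValueError("ka_immobilized must be positive")
    ka_free = ratio * ka_immobilized
    deviation = 100.0 * abs(ka_free - ka_immobilized) / ka_free
    return FreeAffinityResult(ka_free=ka_free, ka_immobilized=ka_immobilized,
                              ratio=ratio, deviation_pct=deviation)


def free_ligand_fraction(params: CompetitiveParams, as_totals) -> np.ndarray:
    """Exact-solver diagnostic: equilibrium free-ligand fraction per level.

    Values above ~0.01 flag levels where the zero-free-ligand closure used by
    :func:`competitive_mass_balance` starts to bias the fitted ratio.
    """
    fractions = []
    for m in np.asarray(as_totals, dtype=float):
        f, _, _ = solve_competitive_equilibrium(float(m), params)
        fractions.append(f / m if m > 0 else 0.0)
    return np.array(fractions)
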