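"""Linearized pseudo-first-order and pseudo-second-order kinetic fits.

PFO: ln(Q_e - Q_t) = ln Q_e - k t, fitted as OLS of ln(Q_e - Q_t) on t;
PSO: t/Q_t = 1/(k Q_e^2) + t/Q_e, fitted as OLS of t/Q_t on t.  The
linearized estimators are the primary ones (mirroring standard adsorption
practice); :func:`nonlinear_refit` offers a clearly-labelled nonlinear
least-squares diagnostic.

Model selection keeps the fit with the highest R^2; an exact tie prefers the
pseudo-second-order model, whose fit quality is conventionally read as
chemisorption being rate-limiting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .datasets import KineticsDataset
from .errors import FitFailureError, InsufficientDataError
from .regression import ols_line
from .simulate import kinetic_uptake

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KineticFit:
    """One kinetic model fit: rate constant, fitted plateau, line diagnostics.

    ``k`` is in h^-1 for PFO and g/(μg·h) for PSO; ``q_e`` in μg/g.
    ``n_excluded`` counts points dropped by the model's domain restriction
    (Q_t >= Q_e for PFO; t <= 0 or Q_t <= 0 for PSO).
    """

    model: str
    k: float
    q_e: float
    slope: float
    intercept: float
    r_squared: float
    n_used: int
    n_excluded: int
    selection_margin: float | None = None

    @property
    def equation(self) -> str:
        if self.model == "PFO":
            return f"ln(Qe-Qt) = {self.intercept:.4g} - {self.k:.4g} t"
        return f"t/Qt = {self.intercept:.4g} + {self.slope:.4g} t"


def fit_pseudo_first_order(ds: KineticsDataset) -> KineticFit:
    """Fit ln(Q_e - Q_t) = ln Q_e - k t by OLS.

    Q_e defaults to the maximum observed Q_t when the dataset carries no
    plateau value.  Points with Q_t >= Q_e (log undefined) are excluded and
    counted, never perturbed; fewer than 3 usable points raises
    :class:`InsufficientDataError`.
    """
    q_e = ds.q_e_observed if ds.q_e_observed is not None else float(np.max(ds.q_t))
    usable = ds.q_t < q_e
    n_excluded = int(np.sum(~usable))
    if n_excluded:
        logger.info("PFO fit: excluded %d point(s) with Q_t >= Q_e", n_excluded)
    if int(np.sum(usable)) < 3:
        raise InsufficientDataError(
            f"PFO fit needs >= 3 points with Q_t < Q_e; have {int(np.sum(usable))}"
        )
    t = ds.t[usable]
    logq = np.log(q_e - ds.q_t[usable])
    line = ols_line(t, logq)
    k = -line.slope
    if not k > 0:
        raise FitFailureError(f"PFO fit produced non-positive rate constant {k:.4g}")
    return KineticFit(
        model="PFO",
        k=k,
        q_e=float(np.exp(line.intercept)),
        slope=line.slope,
        intercept=line.intercept,
        r_squared=line.r_squared,
        n_used=line.n,
        n_excluded=n_excluded,
    )


def fit_pseudo_second_order(ds: KineticsDataset) -> KineticFit:
    """Fit t/Q_t = 1/(k Q_e^2) + t/Q_e by OLS; Q_e = 1/slope, k = slope^2/intercept."""
    usable = (ds.t > 0) & (ds.q_t > 0)
    n_excluded = int(np.sum(~usable))
    if n_excluded:
        logger.info("PSO fit: excluded %d point(s) with t <= 0 or Q_t <= 0", n_excluded)
    if int(np.sum(usable)) < 3:
        raise InsufficientDataError(
            f"PSO fit needs >= 3 points with t > 0 and Q_t > 0; have {int(np.sum(usable))}"
        )
    t = ds.t[usable]
    line = ols_line(t, t / ds.q_t[usable])
    if not line.slope > 0:
        raise FitFailureError(f"PSO fit produced non-positive slope {line.slope:.4g}")
    if not line.intercept > 0:
        raise FitFailureError(
            f"PSO fit produced non-positive intercept {line.intercept:.4g}; "
            "rate constant k = slope^2/intercept is undefined"
        )
    return KineticFit(
        model="PSO",
        k=line.slope**2 / line.intercept,
        q_e=1.0 / line.slope,
        slope=line.slope,
        intercept=line.intercept,
        r_squared=line.r_squared,
        n_used=line.n,
        n_excluded=n_excluded,
    )


def select_kinetic_model(fits: list[KineticFit]) -> KineticFit:
    """Return the fit with the highest R^2; ties prefer PSO.

    The returned fit carries ``selection_margin``: its R^2 minus the
    runner-up's (0 for a single candidate).
    """
    if not fits:
        raise ValueError("need at least one fit to select from")
    ranked = sorted(fits, key=lambda f: (f.r_squared, f.model == "PSO"), reverse=True)
    best = ranked[0]
    margin = best.r_squared - ranked[1].r_squared if len(ranked) > 1 else 0.0
    logger.info("selected %s (R^2 %.4f, margin %.4f)", best.model, best.r_squared, margin)
    return replace(best, selection_margin=margin)


def nonlinear_refit(ds: KineticsDataset, model: str) -> tuple[float, float]:
    """Diagnostic nonlinear least-squares fit; returns (k, q_e).

    This is a cross-check on the primary linearized estimators, started from
    a crude plateau guess; it is never used for reported constants.
    """
    model = model.upper()
    if model not in ("PFO", "PSO"):
        raise ValueError(f"unknown kinetic model: {model!r}")
    q0 = ds.q_e_observed if ds.q_e_observed is not None else float(np.max(ds.q_t))

    def f(t, q_e, k):
        return kinetic_uptake(model, q_e, k, t)

    popt, _ = curve_fit(f, ds.t, ds.q_t, p0=[q0, 0.1],
                        bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=10000)
    q_e, k = popt
    return float(k), float(q_e)
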