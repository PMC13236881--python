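"""Protein-loading capacity, conjugate stability and heavy-metal selectivity.

Three small analyses that characterize an adsorbent preparation rather than
its binding thermodynamics: the maximum number of protein molecules
immobilized per particle (slope of bound protein vs particle molarity over
the linear, sub-saturation regime), the fraction of protein released over
time (covalent-linkage stability), and the retention of ligand adsorption
under competing heavy metals (selectivity).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .datasets import LoadingDataset
from .errors import InsufficientDataError
from .regression import ols_line, select_linear_segment

logger = logging.getLogger(__name__)

#: Default retention threshold (%) above which an adsorbent counts as retaining
#: its capacity under interference; the boundary is inclusive.
RETENTION_THRESHOLD = 95.0


@dataclass(frozen=True)
class LoadingFit:
    """Loading regression: capacity in molecules per sphere (mol/mol slope)."""

    capacity: float
    capacity_sd: float
    intercept: float
    r_squared: float
    segment: tuple[int, int]
    n_points: int


def fit_loading_capacity(ds: LoadingDataset, min_len: int = 4,
                         r2_min: float = 0.99) -> LoadingFit:
    """Slope of bound protein (μM) on sphere molarity (μM) over the linear regime.

    Both axes are molar, so the slope is mol protein per mol sphere —
    molecules per sphere.  Saturated tail points are excluded by the shared
    linear-segment selector when enough points are available; with fewer than
    ``min_len`` points (but >= 3) the full range is fitted.
    """
    if len(ds) < 3:
        raise InsufficientDataError(f"need >= 3 loading points, have {len(ds)}")
    x, y = ds.sphere_conc, ds.protein_bound
    if len(ds) >= min_len:
        segment = select_linear_segment(x, y, min_len=min_len, r2_min=r2_min)
    else:
        segment = (0, len(ds))
    start, stop = segment
    if stop - start < len(ds):
        logger.info("loading fit: %d saturated/nonlinear point(s) excluded",
                    len(ds) - (stop - start))
    line = ols_line(x[start:stop], y[start:stop])
    return LoadingFit(
        capacity=line.slope,
        capacity_sd=line.slope_sd,
        intercept=line.intercept,
        r_squared=line.r_squared,
        segment=segment,
        n_points=stop - start,
    )


@dataclass(frozen=True)
class ReleaseResult:
    """Percent of initially bound protein released at the requested horizon."""

    released_pct: float
    horizon: float
    threshold_pct: float
    passes: bool


def release_fraction(series: Sequence[tuple[float, float]],
                     horizon: float | None = None,
                     threshold_pct: float = 4.0) -> ReleaseResult:
    """Percent released between t = 0 and ``horizon`` (default: last time point).

    ``series`` is (time, bound protein) pairs; a t = 0 entry with positive
    bound amount is required.  Odd inputs where bound increases yield a
    negative release, reported with a warning rather than clipped.
    """
    pairs = sorted((float(t), float(b)) for t, b in series)
    if not pairs or pairs[0][0] != 0.0:
        raise ValueError("series must contain a t = 0 point")
    b0 = pairs[0][1]
    if not b0 > 0:
        raise ValueError("bound amount at t = 0 must be positive")
    if horizon is None:
        horizon = pairs[-1][0]
    eligible = [b for t, b in pairs if t <= horizon]
    bt = eligible[-1]
    released = 100.0 * (b0 - bt) / b0
    if released < 0:
        warnings.warn(f"bound amount increased over time: release {released:.2f}% < 0",
                      stacklevel=2)
    return ReleaseResult(released_pct=released, horizon=horizon,
                         threshold_pct=threshold_pct, passes=released <= threshold_pct)


@dataclass(frozen=True)
class InterferenceRecord:
    """Retention of ligand adsorption for one adsorbent x metal pair."""

    adsorbent: str
    metal: str
    q_with: float
    q_without: float
    retention_pct: float
    retained: bool


def retention(pairs: Iterable[tuple[str, str, float, float]],
              threshold_pct: float = RETENTION_THRESHOLD) -> list[InterferenceRecord]:
    """Retention percentage per (adsorbent, metal, Q_with, Q_without) record.

    retention = 100 x Q_with/Q_without, classified as retained when >= the
    threshold (inclusive, so a boundary value counts as retained).  The
    metric is a ratio, so any consistent adsorption unit (μg/g, %, μM)
    cancels.  Zero or negative controls are errors.
    """
    records = []
    for adsorbent, metal, q_with, q_without in pairs:
        if not q_without > 0:
            raise ValueError(
                f"control adsorption must be positive for {adsorbent}/{metal}, "
                f"got {q_without}"
            )
        if q_with < 0:
            raise ValueError(f"adsorption with metal must be non-negative for "
                             f"{adsorbent}/{metal}, got {q_with}")
        pct = 100.0 * q_with / q_without
        records.append(InterferenceRecord(
            adsorbent=str(adsorbent), metal=str(metal),
            q_with=float(q_with), q_without=float(q_without),
            retention_pct=pct, retained=pct >= threshold_pct))
    return records
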