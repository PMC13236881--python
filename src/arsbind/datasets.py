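"""Typed in-memory containers for the experiment tables the package analyses.

Each container validates its physical invariants on construction (mass
conservation, non-negativity, monotone time axes) so downstream fits can
assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .particles import ARSENIC, AdsorbentSuspension, LigandSpec

_CONSERVATION_RTOL = 1e-9


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class IsothermDataset:
    """Equilibrium binding points at fixed adsorbent concentration.

    ``total``, ``free`` and ``bound`` are parallel arrays of ligand
    concentrations in μM; each point must close its mass balance
    (free + bound = total).  Replicate points share a ``total`` value and can
    be collapsed with :meth:`averaged`.
    """

    total: np.ndarray
    free: np.ndarray
    bound: np.ndarray
    suspension: AdsorbentSuspension
    ligand: LigandSpec = ARSENIC
    label: str = ""
    #: generating parameters, recorded by the simulator for recovery tests
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.total = _as_float_array(self.total, "total")
        self.free = _as_float_array(self.free, "free")
        self.bound = _as_float_array(self.bound, "bound")
        if not (len(self.total) == len(self.free) == len(self.bound)):
            raise ValueError("total, free and bound must have equal length")
        if np.any(self.total < 0) or np.any(self.free < 0) or np.any(self.bound < 0):
            raise ValueError("concentrations must be non-negative")
        tol = _CONSERVATION_RTOL * np.maximum(1.0, self.total)
        bad = np.abs(self.total - self.free - self.bound) > tol
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"mass balance violated at point {i}: "
                f"total={self.total[i]} != free+bound={self.free[i] + self.bound[i]}"
            )

    def __len__(self) -> int:
        return len(self.total)

    def averaged(self) -> "IsothermDataset":
        """Collapse replicate points: mean bound per unique total, free by difference."""
        order: list[float] = []
        for t in self.total:
            if t not in order:
                order.append(t)
        totals, bounds = [], []
        for t in order:
            mask = self.total == t
            totals.append(t)
            bounds.append(float(np.mean(self.bound[mask])))
        totals_arr = np.array(totals)
        bounds_arr = np.minimum(np.array(bounds), totals_arr)
        return IsothermDataset(
            total=totals_arr,
            free=totals_arr - bounds_arr,
            bound=bounds_arr,
            suspension=self.suspension,
            ligand=self.ligand,
            label=self.label,
            params=dict(self.params),
        )


@dataclass
class KineticsDataset:
    """Uptake time course: adsorbed amount Q_t (μg/g) at times t (h).

    ``q_e_observed`` is the experimental plateau, used as the Q_e entering the
    pseudo-first-order log transform when available.
    """

    t: np.ndarray
    q_t: np.ndarray
    q_e_observed: float | None = None
    label: str = ""
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.t = _as_float_array(self.t, "t")
        self.q_t = _as_float_array(self.q_t, "q_t")
        if len(self.t) != len(self.q_t):
            raise ValueError("t and q_t must have equal length")
        if np.any(self.t < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.q_t < 0):
            raise ValueError("adsorbed amounts must be non-negative")
        if self.q_e_observed is not None and not self.q_e_observed > 0:
            raise ValueError("q_e_observed must be positive when supplied")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class CompetitiveDataset:
    """Competition series: total As(III) vs As bound to the immobilized receptor R.

    ``r_total`` is the immobilized site concentration (n x [S], μM);
    ``p_total`` the competing free-protein site concentration (μM).
    """

    as_total: np.ndarray
    r_bound: np.ndarray
    r_total: float
    p_total: float
    label_r: str = "R"
    label_p: str = "P"
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.as_total = _as_float_array(self.as_total, "as_total")
        self.r_bound = _as_float_array(self.r_bound, "r_bound")
        if len(self.as_total) != len(self.r_bound):
            raise ValueError("as_total and r_bound must have equal length")
        if not (self.r_total > 0 and self.p_total > 0):
            raise ValueError("r_total and p_total must be positive")
        if np.any(self.r_bound < 0):
            raise ValueError("r_bound must be non-negative")
        cap = np.minimum(self.as_total, self.r_total)
        tol = _CONSERVATION_RTOL * np.maximum(1.0, cap)
        if np.any(self.r_bound > cap + tol):
            i = int(np.argmax(self.r_bound - cap))
            raise ValueError(
                f"r_bound exceeds min(as_total, r_total) at point {i}: {self.r_bound[i]}"
            )

    def __len__(self) -> int:
        return len(self.as_total)


@dataclass
class LoadingDataset:
    """Protein-loading series: bound protein (μM) vs sphere molarity (μM)."""

    sphere_conc: np.ndarray
    protein_bound: np.ndarray
    protein_total: float
    label: str = ""

    def __post_init__(self):
        self.sphere_conc = _as_float_array(self.sphere_conc, "sphere_conc")
        self.protein_bound = _as_float_array(self.protein_bound, "protein_bound")
        if len(self.sphere_conc) != len(self.protein_bound):
            raise ValueError("sphere_conc and protein_bound must have equal length")
        if not self.protein_total > 0:
            raise ValueError("protein_total must be positive")
        if np.any(self.sphere_conc < 0):
            raise ValueError("sphere concentrations must be non-negative")
        if np.any(self.protein_bound < 0):
            raise ValueError("bound protein must be non-negative")
        if np.any(self.protein_bound > self.protein_total * (1 + _CONSERVATION_RTOL)):
            raise ValueError("bound protein exceeds protein_total")

    def __len__(self) -> int:
        return len(self.sphere_conc)
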