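"""Unit accounting for adsorbent suspensions and ligand concentrations.

A biosilica-sphere suspension is usually described by its mass concentration
(g/L) and a microscopically counted particle density (particles per gram).
Treating each particle as one "molecule" turns the suspension into a molar
reagent: dividing the particle number concentration by Avogadro's constant
yields a particle molarity, and Avogadro's constant over the count per gram
yields a particle molar mass.  These conversions are what let per-particle
binding-site numbers (order 1e7) be expressed on the same micromolar scale as
the dissolved ligand.

All concentrations in this package are carried internally in μM; reports
rescale to display conventions (K_A in 1e6 M^-1, site numbers in 1e7) at the
edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Exact SI value of Avogadro's constant (1/mol).
AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class LigandSpec:
    """A dissolved ligand identified by name and molar (or atomic) mass in g/mol."""

    name: str
    molar_mass: float

    def __post_init__(self):
        if not (self.molar_mass > 0 and math.isfinite(self.molar_mass)):
            raise ValueError(f"molar_mass must be positive and finite, got {self.molar_mass}")


#: Arsenic, the ligand of interest throughout; atomic mass 74.92 g/mol.
ARSENIC = LigandSpec("As", 74.92)


def suspension_molarity(mass_conc: float, particles_per_gram: float) -> float:
    """Molar concentration (μM) of a particle suspension.

    Parameters
    ----------
    mass_conc : float
        Adsorbent mass concentration in g/L.
    particles_per_gram : float
        Counted particle number per gram of adsorbent.

    Returns
    -------
    float
        Particle molarity in μM: ``mass_conc * particles_per_gram / N_A * 1e6``.
    """
    for name, v in (("mass_conc", mass_conc), ("particles_per_gram", particles_per_gram)):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and non-negative, got {v}")
    return mass_conc * particles_per_gram / AVOGADRO * 1e6


def particle_molar_mass(particles_per_gram: float) -> float:
    """Molar mass (g/mol) of a particle species counted at ``particles_per_gram``."""
    if not (particles_per_gram > 0 and math.isfinite(particles_per_gram)):
        raise ValueError(f"particles_per_gram must be positive and finite, got {particles_per_gram}")
    return AVOGADRO / particles_per_gram


def ligand_mass_to_molar(conc_ug_per_L: float, spec: LigandSpec) -> float:
    """Convert a ligand mass concentration (μg/L) to μM using ``spec.molar_mass``.

    μg/L divided by g/mol is μmol/L, i.e. μM, so no scale factor is needed.
    """
    if not math.isfinite(conc_ug_per_L) or conc_ug_per_L < 0:
        raise ValueError(f"concentration must be finite and non-negative, got {conc_ug_per_L}")
    return conc_ug_per_L / spec.molar_mass


def ligand_molar_to_mass(conc_uM: float, spec: LigandSpec) -> float:
    """Inverse of :func:`ligand_mass_to_molar`: μM to μg/L."""
    if not math.isfinite(conc_uM) or conc_uM < 0:
        raise ValueError(f"concentration must be finite and non-negative, got {conc_uM}")
    return conc_uM * spec.molar_mass


@dataclass(frozen=True)
class AdsorbentSuspension:
    """Mass/particle/molar description of an adsorbent-sphere preparation.

    Attributes
    ----------
    mass_conc : float
        g adsorbent per litre (>= 0).
    particles_per_gram : float
        Counted particles per gram (> 0).
    label : str
        Free-text identifier, e.g. ``"S"`` for bare biosilica spheres.
    """

    mass_conc: float
    particles_per_gram: float
    label: str = ""

    def __post_init__(self):
        # Delegate range checks to the conversion functions.
        suspension_molarity(self.mass_conc, self.particles_per_gram)
        particle_molar_mass(self.particles_per_gram)

    @property
    def molar_conc(self) -> float:
        """Particle molarity in μM (mass_conc x particles_per_gram / N_A)."""
        return suspension_molarity(self.mass_conc, self.particles_per_gram)

    @property
    def molar_mass(self) -> float:
        """Particle molar mass in g/mol (N_A / particles_per_gram)."""
        return particle_molar_mass(self.particles_per_gram)

    @classmethod
    def from_molar_conc(cls, molar_conc_uM: float, label: str = "") -> "AdsorbentSuspension":
        """Build a suspension directly from a known particle molarity (μM).

        Convenient when only the molar concentration is reported; a nominal
        1 g/L mass concentration is assumed and the particle count per gram
        back-derived so that round trips are exact.
        """
        if not (molar_conc_uM > 0 and math.isfinite(molar_conc_uM)):
            raise ValueError(f"molar_conc_uM must be positive and finite, got {molar_conc_uM}")
        return cls(mass_conc=1.0, particles_per_gram=molar_conc_uM * 1e-6 * AVOGADRO, label=label)
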