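import numpy as np
import pytest

from arsbind import AdsorbentSuspension
from arsbind.simulate import BindingParams


@pytest.fixture
def reference_suspension() -> AdsorbentSuspension:
    """1.00 g/L of spheres counted at 1.657e11 particles/g (~2.75e-7 μM)."""
    return AdsorbentSuspension(mass_conc=1.00, particles_per_gram=1.657e11, label="S")


@pytest.fixture
def flagship_params(reference_suspension) -> BindingParams:
    """High-affinity conjugate: K_A = 30.49 μM^-1, 2.80e7 sites/particle."""
    return BindingParams(ka=30.49, sites_per_particle=2.80e7,
                         suspension=reference_suspension)


@pytest.fixture
def moderate_params(reference_suspension) -> BindingParams:
    """Moderate-affinity system where the titration design resolves K_D."""
    return BindingParams(ka=0.812, sites_per_particle=0.83e7,
                         suspension=reference_suspension)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
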