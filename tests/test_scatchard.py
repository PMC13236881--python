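"""Scatchard transform, linear-segment selection and affinity estimation."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from arsbind import (
    AdsorbentSuspension,
    IsothermDataset,
    affinity_from_isotherm,
    affinity_from_line,
    scatchard_fit,
    scatchard_transform,
    select_linear_segment,
    simulate_isotherm,
)
from arsbind.errors import (
    AffinityUndefinedError,
    InsufficientDataError,
    NoLinearSegmentError,
)
from arsbind.regression import ols_line
from arsbind.scatchard import ScatchardPoint
from arsbind.simulate import BindingParams, NoiseModel


def make_isotherm(total, free, bound, molar_conc=2.753e-7):
    return IsothermDataset(
        total=np.asarray(total), free=np.asarray(free), bound=np.asarray(bound),
        suspension=AdsorbentSuspension.from_molar_conc(molar_conc, label="S"))


class TestTransform:
    def test_hand_computed_point(self):
        # bound 2.753 μM on 2.753e-7 μM particles: occupancy 1e7, scaled 1.0
        ds = make_isotherm([3.253], [0.5], [2.753])
        (p,) = scatchard_transform(ds)
        assert p.mu_scaled == pytest.approx(1.0, rel=1e-12)
        assert p.y == pytest.approx(0.5, rel=1e-12)

    def test_zero_bound_points_skipped_with_warning(self):
        ds = make_isotherm([1.0, 3.253], [1.0, 0.5], [0.0, 2.753])
        with pytest.warns(UserWarning, match="zero-bound"):
            points = scatchard_transform(ds)
        assert len(points) == 1

    def test_all_zero_bound_is_insufficient(self):
        ds = make_isotherm([1.0], [1.0], [0.0])
        with pytest.raises(InsufficientDataError):
            scatchard_transform(ds)

    def test_doubling_particle_molarity_halves_occupancy(self):
        p1 = scatchard_transform(make_isotherm([3.0], [0.5], [2.5], 2.753e-7))[0]
        p2 = scatchard_transform(make_isotherm([3.0], [0.5], [2.5], 2 * 2.753e-7))[0]
        assert p2.mu_scaled == pytest.approx(p1.mu_scaled / 2, rel=1e-12)


class TestAffinityFromLine:
    @pytest.mark.parametrize("slope, intercept, ka, n", [
        (0.3567, 0.0117, 30.49, 2.80),   # high-affinity conjugate
        (1.2027, 1.4811, 0.812, 0.83),   # weak As(V) binding
        (1.0, 1.0, 1.0, 1.0),            # unit case
    ])
    def test_published_style_rows(self, slope, intercept, ka, n):
        got_ka, got_n = affinity_from_line(slope, intercept)
        assert got_ka == pytest.approx(ka, abs=0.005 if ka > 10 else 0.0005)
        assert got_n == pytest.approx(n, abs=0.005)

    def test_nonpositive_intercept_is_undefined(self):
        with pytest.raises(AffinityUndefinedError):
            affinity_from_line(0.5, 0.0)


class TestSegmentSelection:
    def test_collinear_points_return_full_range(self):
        x = np.linspace(0.1, 5, 8)
        assert select_linear_segment(x, 0.35 * x + 0.01) == (0, 8)

    def test_gross_outlier_excluded(self):
        x = np.linspace(0.1, 5, 8)
        y = 0.35 * x + 0.01
        y[-1] += 50.0  # many SD off the line
        start, stop = select_linear_segment(x, y)
        assert (start, stop) == (0, 7)

    def test_matches_exhaustive_oracle(self, rng):
        x = np.linspace(0, 10, 12)
        y = 2 * x + 1 + rng.normal(0, 0.5, size=12)
        min_len, r2_min = 4, 0.95
        # brute-force oracle over every window with the documented tie-breaks
        best = None
        for i in range(len(x)):
            for j in range(i + min_len, len(x) + 1):
                r2 = ols_line(x[i:j], y[i:j]).r_squared
                if r2 >= r2_min:
                    key = (j - i, r2, -i)
                    if best is None or key > best[0]:
                        best = (key, (i, j))
        assert select_linear_segment(x, y, min_len, r2_min) == best[1]

    def test_no_qualifying_run_raises_with_diagnostics(self, rng):
        x = np.linspace(0, 1, 6)
        y = rng.normal(size=6) * 100
        with pytest.raises(NoLinearSegmentError) as err:
            select_linear_segment(x, y, min_len=4, r2_min=0.999)
        assert err.value.best is not None


class TestFit:
    def test_noiseless_langmuir_is_exactly_linear_and_recovers_parameters(
            self, flagship_params):
        ds = simulate_isotherm(flagship_params,
                               flagship_params.capacity * np.geomspace(0.5, 3, 10))
        fit = affinity_from_isotherm(ds)
        assert fit.segment == (0, 10)  # whole set qualifies
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.ka == pytest.approx(flagship_params.ka, rel=1e-6)
        assert fit.n_sites == pytest.approx(flagship_params.sites_per_particle, rel=1e-6)
        # fitted capacity bounds the largest observed bound amount
        assert fit.n_sites * ds.suspension.molar_conc >= np.max(ds.bound) * (1 - 1e-9)

    def test_agrees_with_independent_nonlinear_langmuir_fit(self, moderate_params):
        ds = simulate_isotherm(moderate_params,
                               moderate_params.capacity * np.geomspace(0.5, 3, 8))
        fit = affinity_from_isotherm(ds)

        def langmuir(f, cap, ka):
            return cap * ka * f / (1 + ka * f)

        (cap, ka), _ = curve_fit(langmuir, ds.free, ds.bound, p0=[1.0, 1.0])
        assert fit.ka == pytest.approx(ka, rel=5e-3)
        assert fit.n_sites * ds.suspension.molar_conc == pytest.approx(cap, rel=5e-3)

    def test_scale_invariance_of_site_number(self, moderate_params):
        c = 3.7
        ds = simulate_isotherm(moderate_params,
                               moderate_params.capacity * np.geomspace(0.5, 3, 8))
        scaled = IsothermDataset(
            total=ds.total * c, free=ds.free * c, bound=ds.bound * c,
            suspension=AdsorbentSuspension.from_molar_conc(
                ds.suspension.molar_conc * c))
        fit, fit_scaled = affinity_from_isotherm(ds), affinity_from_isotherm(scaled)
        assert fit_scaled.n_sites == pytest.approx(fit.n_sites, rel=1e-9)
        assert fit_scaled.ka == pytest.approx(fit.ka / c, rel=1e-9)

    def test_replicates_are_averaged_before_transform(self, moderate_params):
        noisy = simulate_isotherm(
            moderate_params, moderate_params.capacity * np.geomspace(0.5, 3, 8),
            noise=NoiseModel(seed=5), replicates=3)
        fit = affinity_from_isotherm(noisy)
        assert fit.n_points <= 8  # one point per concentration after averaging

    def test_intercept_through_origin_is_affinity_undefined(self):
        pts = [ScatchardPoint(x, 1.0, 0.4 * x - 0.5) for x in np.linspace(2, 5, 6)]
        with pytest.raises(AffinityUndefinedError) as err:
            scatchard_fit(pts)
        assert err.value.diagnostics.slope == pytest.approx(0.4, rel=1e-9)

    def test_too_few_points(self):
        pts = [ScatchardPoint(1.0, 1.0, 1.0), ScatchardPoint(2.0, 1.0, 2.0)]
        with pytest.raises(InsufficientDataError):
            scatchard_fit(pts)

    def test_delta_method_sds_cover_noisy_recovery(self, moderate_params):
        # with noise, |ka_hat - ka_true| should be within a few delta-method SDs
        design = moderate_params.capacity * np.geomspace(0.5, 3, 10)
        ds = simulate_isotherm(moderate_params, design,
                               noise=NoiseModel(seed=11), replicates=3)
        fit = affinity_from_isotherm(ds)
        assert abs(fit.ka - moderate_params.ka) < 5 * fit.ka_sd

    def test_blank_correction_subtracts_control_binding(self, moderate_params):
        design = moderate_params.capacity * np.geomspace(0.5, 3, 8)
        ds = simulate_isotherm(moderate_params, design)
        # a blank that binds nothing leaves the fit unchanged
        blank = IsothermDataset(total=design, free=design, bound=np.zeros_like(design),
                                suspension=ds.suspension)
        fit_plain = affinity_from_isotherm(ds)
        fit_blanked = affinity_from_isotherm(ds, blank=blank)
        assert fit_blanked.ka == pytest.approx(fit_plain.ka, rel=1e-12)
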