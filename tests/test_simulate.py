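"""Equilibrium solvers and forward simulators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arsbind import (
    kinetic_uptake,
    simulate_competitive_series,
    simulate_isotherm,
    simulate_kinetics,
    solve_competitive_equilibrium,
    solve_single_equilibrium,
)
from arsbind.simulate import BindingParams, CompetitiveParams, NoiseModel


def bisect_single(m_total, capacity, ka, tol=1e-14):
    """Independent bisection oracle for the scalar Langmuir equation."""
    def g(f):
        return f + capacity * ka * f / (1 + ka * f) - m_total
    lo, hi = 0.0, m_total
    while hi - lo > tol * max(1.0, m_total):
        mid = (lo + hi) / 2
        if g(mid) > 0:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2


class TestSingleEquilibrium:
    def test_golden_ratio_case(self):
        free, bound = solve_single_equilibrium(1.0, 1.0, 1.0)
        assert free == pytest.approx((math.sqrt(5) - 1) / 2, rel=1e-12)
        assert bound == pytest.approx(1 - (math.sqrt(5) - 1) / 2, rel=1e-12)

    def test_no_ligand(self):
        assert solve_single_equilibrium(0.0, 5.0, 2.0) == (0.0, 0.0)

    def test_saturation_limit(self):
        free, bound = solve_single_equilibrium(2.0, 1.0, 1e12)
        assert bound == pytest.approx(1.0, rel=1e-9)
        assert free == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("ka", np.geomspace(1e-3, 1e3, 13))
    @pytest.mark.parametrize("m_total", [0.1, 1.0, 10.0])
    def test_agrees_with_bisection_oracle(self, ka, m_total):
        capacity = 2.5
        free, bound = solve_single_equilibrium(m_total, capacity, ka)
        assert free == pytest.approx(bisect_single(m_total, capacity, ka), rel=1e-10)
        assert free + bound == m_total  # conservation exact by construction

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            solve_single_equilibrium(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            solve_single_equilibrium(1.0, 1.0, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(m=st.floats(1e-6, 1e3), cap=st.floats(1e-6, 1e3),
           ka=st.floats(1e-4, 1e4), delta=st.floats(1e-6, 10.0))
    def test_bound_monotone_in_total_ka_capacity(self, m, cap, ka, delta):
        _, b0 = solve_single_equilibrium(m, cap, ka)
        assert solve_single_equilibrium(m + delta, cap, ka)[1] >= b0 - 1e-12
        assert solve_single_equilibrium(m, cap + delta, ka)[1] >= b0 - 1e-12
        assert solve_single_equilibrium(m, cap, ka * (1 + delta))[1] >= b0 - 1e-12


class TestCompetitiveEquilibrium:
    def test_symmetric_case_closed_form(self):
        # KD1 = KD2 = R_t = P_t = 1, total 1: free solves f^2 + 2f - 1 = 0
        free, rb, pb = solve_competitive_equilibrium(
            1.0, CompetitiveParams(kd1=1, kd2=1, r_total=1, p_total=1))
        assert free == pytest.approx(math.sqrt(2) - 1, rel=1e-12)
        assert rb == pytest.approx(pb, rel=1e-12)
        assert rb == pytest.approx((1 - (math.sqrt(2) - 1)) / 2, rel=1e-12)

    def test_zero_ligand(self):
        assert solve_competitive_equilibrium(
            0.0, CompetitiveParams(1, 1, 1, 1)) == (0.0, 0.0, 0.0)

    def test_reduces_to_single_receptor_when_competitor_vanishes(self):
        params = CompetitiveParams(kd1=0.5, kd2=1.0, r_total=2.0, p_total=1e-12)
        free_c, rb, _ = solve_competitive_equilibrium(1.5, params)
        free_s, bound_s = solve_single_equilibrium(1.5, 2.0, 1 / 0.5)
        assert free_c == pytest.approx(free_s, rel=1e-9)
        assert rb == pytest.approx(bound_s, rel=1e-9)

    def test_conservation_and_residual(self):
        params = CompetitiveParams(kd1=0.03, kd2=0.06, r_total=7.7, p_total=7.85)
        for total in [0.5, 2.0, 7.0, 20.0]:
            free, rb, pb = solve_competitive_equilibrium(total, params)
            assert free + rb + pb == pytest.approx(total, rel=1e-12)

    def test_equal_affinities_split_bound_by_site_ratio(self):
        params = CompetitiveParams(kd1=0.2, kd2=0.2, r_total=3.0, p_total=1.0)
        _, rb, pb = solve_competitive_equilibrium(2.0, params)
        assert rb / pb == pytest.approx(3.0, rel=1e-10)


class TestSimulateIsotherm:
    def test_noiseless_points_satisfy_langmuir_relation(self, flagship_params):
        ds = simulate_isotherm(flagship_params, [1.0, 3.0, 8.0, 12.0])
        cap, ka = flagship_params.capacity, flagship_params.ka
        for f, b in zip(ds.free, ds.bound):
            assert b == pytest.approx(cap * ka * f / (1 + ka * f), rel=1e-9)
        assert np.allclose(ds.total, ds.free + ds.bound)  # conservation

    def test_seed_determinism(self, moderate_params):
        kw = dict(noise=NoiseModel(seed=7), replicates=3)
        a = simulate_isotherm(moderate_params, [1.0, 2.0, 4.0], **kw)
        b = simulate_isotherm(moderate_params, [1.0, 2.0, 4.0], **kw)
        assert np.array_equal(a.bound, b.bound)  # bit-identical

    def test_records_generating_parameters(self, flagship_params):
        ds = simulate_isotherm(flagship_params, [1.0])
        assert ds.params["ka_per_uM"] == flagship_params.ka
        assert ds.params["capacity_uM"] == flagship_params.capacity

    def test_rejects_bad_levels_and_missing_seed(self, flagship_params):
        with pytest.raises(ValueError):
            simulate_isotherm(flagship_params, [])
        with pytest.raises(ValueError):
            simulate_isotherm(flagship_params, [0.0, 1.0])
        with pytest.raises(ValueError):
            simulate_isotherm(flagship_params, [1.0], noise=NoiseModel())  # no seed


class TestSimulateKinetics:
    def test_pso_closed_form_midpoint(self):
        # Q_e^2 k t / (1 + Q_e k t) with Q_e k t = 1 gives Q_e/2
        assert kinetic_uptake("PSO", 100.0, 0.001, 10.0) == pytest.approx(50.0)

    def test_zero_time_and_asymptote(self):
        assert kinetic_uptake("PFO", 80.0, 0.3, 0.0) == 0.0
        assert kinetic_uptake("PSO", 80.0, 0.3, 0.0) == 0.0
        assert kinetic_uptake("PFO", 80.0, 0.3, 1e6) == pytest.approx(80.0, rel=1e-12)
        assert kinetic_uptake("PSO", 80.0, 0.3, 1e9) == pytest.approx(80.0, rel=1e-6)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            simulate_kinetics("elovich", 10.0, 0.1, [1.0, 2.0, 3.0])

    def test_plateau_recorded(self):
        ds = simulate_kinetics("PFO", 80.0, 0.3, [1.0, 2.0, 4.0])
        assert ds.q_e_observed == 80.0


class TestSimulateCompetitiveSeries:
    def test_noiseless_matches_exact_solver(self):
        params = CompetitiveParams(kd1=0.05, kd2=0.1, r_total=5.0, p_total=5.0)
        totals = [0.5, 1.5, 3.0]
        ds = simulate_competitive_series(params, totals)
        for total, rb in zip(ds.as_total, ds.r_bound):
            assert rb == pytest.approx(
                solve_competitive_equilibrium(total, params)[1], rel=1e-12)

    def test_seed_determinism(self):
        params = CompetitiveParams(kd1=0.05, kd2=0.1, r_total=5.0, p_total=5.0)
        a = simulate_competitive_series(params, [1.0, 2.0], noise=NoiseModel(seed=3))
        b = simulate_competitive_series(params, [1.0, 2.0], noise=NoiseModel(seed=3))
        assert np.array_equal(a.r_bound, b.r_bound)


def test_noise_model_validation():
    with pytest.raises(ValueError):
        NoiseModel(kind="additive")
    with pytest.raises(ValueError):
        NoiseModel(cv=-0.1)
    assert NoiseModel.none().make_rng() is None


def test_noise_clamps_negative_draws_to_zero():
    noise = NoiseModel(cv=50.0, seed=0)  # absurd cv forces negative draws
    rng = noise.make_rng()
    values = [noise.apply(1.0, rng) for _ in range(200)]
    assert min(values) == 0.0
    assert all(v >= 0 for v in values)
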