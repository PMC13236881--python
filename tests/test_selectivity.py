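"""Loading capacity, release stability and heavy-metal retention."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arsbind import (
    LoadingDataset,
    fit_loading_capacity,
    release_fraction,
    retention,
)
from arsbind.errors import InsufficientDataError

SLOPE = 2.733e7  # molecules per sphere
PROTEIN_TOTAL = 2.157  # μM


def linear_loading(n=6, total=PROTEIN_TOTAL):
    conc = np.linspace(0.0, 7e-8, n)
    return LoadingDataset(sphere_conc=conc, protein_bound=SLOPE * conc,
                          protein_total=total)


class TestLoading:
    def test_noiseless_slope_recovery(self):
        fit = fit_loading_capacity(linear_loading())
        assert fit.capacity == pytest.approx(SLOPE, rel=1e-6)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_saturated_tail_excluded_by_segment_selector(self):
        conc = np.linspace(0.0, 7e-8, 6)
        bound = SLOPE * conc
        conc_full = np.concatenate([conc, [2e-7, 3e-7, 3.4e-7]])
        bound_full = np.concatenate([bound, [0.93 * PROTEIN_TOTAL] * 3])  # plateau
        ds = LoadingDataset(sphere_conc=conc_full, protein_bound=bound_full,
                            protein_total=PROTEIN_TOTAL)
        fit = fit_loading_capacity(ds)
        assert fit.segment == (0, 6)
        assert fit.capacity == pytest.approx(SLOPE, rel=1e-6)

    def test_long_plateau_never_outcompetes_the_linear_regime(self):
        # even when the flat saturated tail is the longer run, the selector
        # must return the rising linear segment
        conc = np.concatenate([np.linspace(1e-8, 6e-8, 4),
                               np.linspace(2e-7, 3.4e-7, 6)])
        bound = np.minimum(SLOPE * conc, 0.93 * PROTEIN_TOTAL)
        ds = LoadingDataset(sphere_conc=conc, protein_bound=bound,
                            protein_total=PROTEIN_TOTAL)
        fit = fit_loading_capacity(ds)
        assert fit.segment == (0, 4)
        assert fit.capacity == pytest.approx(SLOPE, rel=1e-6)

    def test_noisy_recovery_within_delta_method_error(self, rng):
        conc = np.linspace(1e-8, 7e-8, 8)
        bound = SLOPE * conc * (1 + 0.02 * rng.standard_normal(8))
        ds = LoadingDataset(sphere_conc=conc, protein_bound=bound,
                            protein_total=PROTEIN_TOTAL)
        fit = fit_loading_capacity(ds, r2_min=0.95)
        assert abs(fit.capacity - SLOPE) < 3 * fit.capacity_sd

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_loading_capacity(linear_loading(n=2))


class TestRelease:
    def test_three_percent_release_passes_threshold(self):
        res = release_fraction([(0.0, 100.0), (30.0, 98.5), (60.0, 97.0)], horizon=60.0)
        assert res.released_pct == pytest.approx(3.0)
        assert res.passes

    def test_constant_series_releases_nothing(self):
        res = release_fraction([(0.0, 50.0), (60.0, 50.0)])
        assert res.released_pct == 0.0

    def test_increasing_bound_reports_negative_release_with_warning(self):
        with pytest.warns(UserWarning, match="increased"):
            res = release_fraction([(0.0, 100.0), (60.0, 104.0)])
        assert res.released_pct == pytest.approx(-4.0)

    def test_nondecreasing_release_for_monotone_decay(self):
        series = [(t, 100.0 * np.exp(-0.001 * t)) for t in range(0, 70, 10)]
        released = [release_fraction(series, horizon=h).released_pct
                    for h in (10, 30, 60)]
        assert all(r >= 0 for r in released)
        assert released == sorted(released)

    def test_missing_time_zero(self):
        with pytest.raises(ValueError):
            release_fraction([(1.0, 100.0), (60.0, 97.0)])


class TestRetention:
    def test_unchanged_adsorption_is_fully_retained(self):
        (rec,) = retention([("S-conj", "Cu", 85.0, 85.0)])
        assert rec.retention_pct == 100.0
        assert rec.retained

    def test_published_style_decrease_not_retained(self):
        # a 21.3% decrease corresponds to 78.7% retention, below threshold
        (rec,) = retention([("S", "mix", 78.7, 100.0)])
        assert rec.retention_pct == pytest.approx(78.7)
        assert not rec.retained

    def test_threshold_is_inclusive(self):
        (rec,) = retention([("x", "Zn", 95.0, 100.0)])
        assert rec.retained

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            retention([("x", "Zn", 10.0, 0.0)])

    @settings(max_examples=50, derandomize=True)
    @given(q_with=st.floats(0.0, 1e3), q_without=st.floats(1e-3, 1e3),
           scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, q_with, q_without, scale):
        (a,) = retention([("x", "m", q_with, q_without)])
        (b,) = retention([("x", "m", q_with * scale, q_without * scale)])
        assert b.retention_pct == pytest.approx(a.retention_pct, rel=1e-9)
        assert a.retained == b.retained
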