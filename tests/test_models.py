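"""Core forward models against closed-form values and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

import glymphkit as gk
from glymphkit import models as m

from oracles import (
    crank_nicolson_slab,
    hemisphere_moles_quadrature,
    mc_flow_moles,
    total_mass_quadrature,
)

SRC_UNIT = gk.GaussianSource(c_peak=1.0, sigma=1.0)
TP_UNIT = gk.TransportParams(d_tissue=1.0)


class TestConcentrationProfile:
    def test_identity_at_origin(self):
        assert m.concentration_profile(0.0, 0.0, SRC_UNIT, TP_UNIT) == pytest.approx(1.0)

    def test_closed_form_at_half_width_time(self):
        # at t = sigma^2 / (2 D) the peak has fallen to 2^(-3/2)
        val = m.concentration_profile(0.0, 0.5, SRC_UNIT, TP_UNIT)
        assert val == pytest.approx(2.0**-1.5, rel=1e-12)

    @pytest.mark.parametrize("r,t", [(-1.0, 0.0), (0.0, -1.0), (np.nan, 0.0), (0.0, np.inf)])
    def test_domain_errors(self, r, t):
        with pytest.raises(ValueError):
            m.concentration_profile(r, t, SRC_UNIT, TP_UNIT)

    def test_total_mass_conserved(self):
        src = gk.GaussianSource(c_peak=2.5, sigma=180.0)
        tp = gk.TransportParams(d_tissue=32.0)
        masses = [total_mass_quadrature(src, tp, t) for t in (0.0, 1e3, 1e5)]
        assert np.ptp(masses) <= 1e-6 * masses[0]

    @settings(max_examples=30, deadline=None)
    @given(r1=st.floats(0, 500), r2=st.floats(0, 500), t=st.floats(0, 1e5))
    def test_monotone_decreasing_in_distance(self, r1, r2, t):
        src = gk.GaussianSource(1.0, 150.0)
        tp = gk.TransportParams(d_tissue=50.0)
        lo, hi = sorted((r1, r2))
        assert m.concentration_profile(hi, t, src, tp) <= m.concentration_profile(lo, t, src, tp) + 1e-15


class TestMolesInHemisphere:
    def test_initial_value_matches_shell_quadrature(self):
        # R = sigma = 1, c_peak = 1: numerical shell integration gives 2 pi * 0.249093
        val = m.moles_in_hemisphere(0.0, SRC_UNIT, TP_UNIT)
        assert val == pytest.approx(hemisphere_moles_quadrature(SRC_UNIT, TP_UNIT, 1.0, 0.0), rel=1e-9)
        assert val == pytest.approx(2.0 * np.pi * 0.249093, rel=1e-5)

    def test_matches_quadrature_over_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            src = gk.GaussianSource(c_peak=rng.uniform(0.1, 5), sigma=rng.uniform(50, 500))
            tp = gk.TransportParams(d_tissue=rng.uniform(10, 500))
            R = rng.uniform(0.5, 3.0) * src.sigma
            t = rng.uniform(0.0, 1e4)
            geo = gk.DetectionGeometry(R)
            got = m.moles_in_hemisphere(t, src, tp, geo)
            want = hemisphere_moles_quadrature(src, tp, R, t)
            assert got == pytest.approx(want, rel=1e-6)

    def test_dilution_limit_and_monotone_decay(self):
        t = np.geomspace(1.0, 1e8, 40)
        vals = m.moles_in_hemisphere(t, SRC_UNIT, TP_UNIT)
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 1e-9 * vals[0]

    def test_infinite_radius_gives_conserved_total(self):
        src = gk.GaussianSource(1.3, 120.0)
        tp = gk.TransportParams(d_tissue=45.0)
        geo = gk.DetectionGeometry(radius_r_detect=1e9)
        total = 2.0 * np.pi * np.sqrt(np.pi / 2.0) * src.c_peak * src.sigma**3
        for t in (0.0, 1e3, 1e5):
            assert m.moles_in_hemisphere(t, src, tp, geo) == pytest.approx(total, rel=1e-9)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            gk.DetectionGeometry(radius_r_detect=0.0)


class TestMolesWithFlow:
    src = gk.GaussianSource(1.0, 150.0)
    tp = gk.TransportParams(d_tissue=32.0)
    geo = gk.DetectionGeometry(150.0)

    def test_no_flow_reduces_to_closed_form(self):
        still = gk.FlowField(0.0)
        for t in (0.0, 60.0, 3600.0):
            got = m.moles_with_flow(t, self.src, self.tp, self.geo, still)
            want = m.moles_in_hemisphere(t, self.src, self.tp, self.geo)
            assert got == pytest.approx(want, rel=1e-9)

    def test_strictly_decreasing_in_velocity(self):
        t = 600.0
        vals = [m.moles_with_flow(t, self.src, self.tp, self.geo, gk.FlowField(v))
                for v in (0.0, 0.5, 2.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_matches_monte_carlo_advected_source(self):
        t, v = 600.0, 0.5
        got = m.moles_with_flow(t, self.src, self.tp, self.geo, gk.FlowField(v))
        mc = mc_flow_moles(self.src, self.tp, 150.0, v, t, n_samples=10_000_000, seed=11)
        assert got == pytest.approx(mc, rel=1e-3)


class TestSlabEfflux:
    geo = gk.SlabGeometry(thickness_l=1.0, position_x=0.0, c0=1.0)

    def test_initial_condition(self):
        assert m.slab_efflux_concentration(0.0, self.geo, TP_UNIT) == pytest.approx(1.0)

    def test_value_at_characteristic_time_vs_pde(self):
        # Dt/L^2 = 0.1 at the impermeable face, Crank-Nicolson oracle
        want = crank_nicolson_slab([0.1], 0.0)[0]
        got = m.slab_efflux_concentration(0.1, self.geo, TP_UNIT)
        assert got == pytest.approx(want, rel=1e-4)
        assert got == pytest.approx(0.9493, abs=2e-4)

    def test_matches_crank_nicolson_over_time_range(self):
        taus = np.geomspace(0.01, 2.0, 9)
        series = m.slab_efflux_concentration(taus, self.geo, TP_UNIT)
        pde = crank_nicolson_slab(taus, 0.0)
        assert np.max(np.abs(series - pde) / np.abs(series)) <= 1e-4

    def test_insensitive_to_position_near_barrier(self):
        # reading at x = 0.1 L instead of at the barrier changes the curve by
        # under 1 % of c0 everywhere; the late-time relative offset tends to
        # the single-mode value 1 - cos(pi x / 2L) ~ 1.23 %
        taus = np.linspace(0.01, 2.0, 100)
        geo_x = gk.SlabGeometry(thickness_l=1.0, position_x=0.1, c0=1.0)
        at0 = m.slab_efflux_concentration(taus, self.geo, TP_UNIT)
        atx = m.slab_efflux_concentration(taus, geo_x, TP_UNIT)
        assert np.max(np.abs(atx - at0)) <= 0.01
        assert np.max(np.abs(atx - at0) / at0) <= 1.0 - np.cos(np.pi * 0.05) + 1e-6

    def test_bounded_and_domain_error(self):
        taus = np.linspace(0.0, 3.0, 50)
        vals = m.slab_efflux_concentration(taus, self.geo, TP_UNIT)
        assert np.all((vals >= -1e-12) & (vals <= 1.0 + 1e-12))
        with pytest.raises(ValueError):
            m.slab_efflux_concentration(-1.0, self.geo, TP_UNIT)


class TestClearanceKinetics:
    src = gk.GaussianSource(1.0, 250.0)
    tp = gk.TransportParams(d_tissue=230.7)

    def test_no_clearance_limit(self):
        cl = gk.ClearanceModel(tau=1e12)
        t = np.linspace(0.0, 1e5, 50)
        plain = m.concentration_profile(3335.0, t, self.src, self.tp)
        cleared = m.clearance_concentration(3335.0, t, self.src, self.tp, cl)
        assert np.allclose(cleared, plain, rtol=1e-6)
        cl_inf = gk.ClearanceModel(tau=np.inf)
        assert np.allclose(
            m.clearance_concentration(3335.0, t, self.src, self.tp, cl_inf), plain, rtol=1e-12)

    def test_survival_ratio_identity(self):
        cl = gk.ClearanceModel(tau=1800.0)
        rng = np.random.default_rng(0)
        r = rng.uniform(0, 5000, 20)
        t = rng.uniform(1.0, 1e5, 20)
        ratio = (m.clearance_concentration(r, t, self.src, self.tp, cl)
                 / m.concentration_profile(r, t, self.src, self.tp))
        assert np.allclose(ratio, cl.tau / (t + cl.tau), rtol=1e-14)

    def test_cleared_peak_earlier_than_uncleared(self):
        cl = gk.ClearanceModel(tau=1800.0)
        t = np.linspace(0.0, 5e4, 20001)
        cleared = m.clearance_concentration(3335.0, t, self.src, self.tp, cl)
        plain = m.concentration_profile(3335.0, t, self.src, self.tp)
        assert t[np.argmax(cleared)] < t[np.argmax(plain)]

    @pytest.mark.parametrize("t,expected", [(0.0, 0.0), (1800.0, 50.0), (3 * 1800.0, 75.0)])
    def test_percent_clearance_values(self, t, expected):
        cl = gk.ClearanceModel(tau=1800.0)
        assert m.clearance_percent(t, cl) == pytest.approx(expected)

    @settings(max_examples=30, deadline=None)
    @given(t1=st.floats(0, 1e7), t2=st.floats(0, 1e7), tau=st.floats(1.0, 1e6))
    def test_percent_clearance_monotone_bounded(self, t1, t2, tau):
        cl = gk.ClearanceModel(tau=tau)
        lo, hi = sorted((t1, t2))
        p_lo, p_hi = m.clearance_percent(lo, cl), m.clearance_percent(hi, cl)
        assert 0.0 <= p_lo <= p_hi < 100.0


class TestConversions:
    def test_tortuosity_identity(self):
        assert m.tortuosity(100.0, 100.0) == pytest.approx(1.0)

    def test_in_vivo_tortuosity_chain(self):
        d_aq_37 = m.stokes_einstein_correct(136.0, 20.0, 37.0)
        assert m.tortuosity(32.1, d_aq_37) == pytest.approx(2.5, abs=0.05)

    def test_implied_tissue_coefficient(self):
        d_aq_37 = m.stokes_einstein_correct(295.0, 20.0, 37.0)
        assert d_aq_37 / 1.4**2 == pytest.approx(230.7, rel=2e-3)

    def test_stokes_einstein_fixed_point_and_anchors(self):
        assert m.stokes_einstein_correct(100.0, 25.0, 25.0) == pytest.approx(100.0)
        # hand computation from the viscosity table nodes
        want_136 = 136.0 * (310.15 / 293.15) * (1.0016 / 0.6913)
        assert m.stokes_einstein_correct(136.0, 20.0, 37.0) == pytest.approx(want_136, rel=1e-12)
        assert m.stokes_einstein_correct(136.0, 20.0, 37.0) == pytest.approx(208.5, rel=1e-3)
        assert m.stokes_einstein_correct(295.0, 20.0, 37.0) == pytest.approx(452.2, rel=1e-3)

    def test_temperature_out_of_range(self):
        with pytest.raises(ValueError):
            m.stokes_einstein_correct(100.0, -5.0, 37.0)
        with pytest.raises(ValueError):
            m.stokes_einstein_correct(100.0, 20.0, 110.0)

    def test_inconsistent_transport_params_rejected(self):
        with pytest.raises(ValueError):
            gk.TransportParams(d_tissue=30.0, d_aq=208.5, lambda_tort=2.0)
        tp = gk.TransportParams.from_aqueous(208.5, 2.5)
        assert tp.d_tissue == pytest.approx(208.5 / 6.25)


class TestPeakArrivalTime:
    def test_boundary_returns_zero(self):
        src = gk.GaussianSource(1.0, 100.0)
        geo = gk.DetectionGeometry(100.0, distance_r=100.0 * np.sqrt(3.0))
        assert m.peak_arrival_time(geo, src, TP_UNIT) == 0.0
        geo_inside = gk.DetectionGeometry(100.0, distance_r=50.0)
        assert m.peak_arrival_time(geo_inside, src, TP_UNIT) == 0.0

    def test_agrees_with_grid_maximization(self):
        src = gk.GaussianSource(1.0, 250.0)
        tp = gk.TransportParams(d_tissue=230.7)
        geo = gk.DetectionGeometry(250.0, distance_r=3335.0)
        analytic = m.peak_arrival_time(geo, src, tp)
        t = np.linspace(1.0, 4.0 * analytic, 400_001)
        grid = t[np.argmax(m.concentration_profile(3335.0, t, src, tp))]
        assert analytic == pytest.approx(grid, rel=1e-3)
        assert analytic == pytest.approx(7.90e3, rel=1e-2)

    def test_inverse_scaling_with_diffusion(self):
        src = gk.GaussianSource(1.0, 10.0)
        geo = gk.DetectionGeometry(10.0, distance_r=3000.0)
        t1 = m.peak_arrival_time(geo, src, gk.TransportParams(d_tissue=50.0))
        t2 = m.peak_arrival_time(geo, src, gk.TransportParams(d_tissue=100.0))
        assert t1 == pytest.approx(2.0 * t2, rel=1e-12)


class TestRecoveryIntensity:
    mapping = gk.BleachMapping(i0=0.2, i_inf=1.0)
    src = gk.GaussianSource(1.0, 150.0)
    tp = gk.TransportParams(d_tissue=136.0)

    def test_endpoints_and_monotonicity(self):
        t = np.linspace(0.0, 5e4, 200)
        vals = m.recovery_intensity(t, self.mapping, self.src, self.tp)
        assert vals[0] == pytest.approx(0.2)
        assert vals[-1] == pytest.approx(1.0, abs=1e-3)  # t^(-3/2) tail
        assert np.all(np.diff(vals) >= 0)

    def test_half_recovery_at_half_moles(self):
        geo = gk.DetectionGeometry.matched(self.src)
        m0 = m.moles_in_hemisphere(0.0, self.src, self.tp, geo)
        t_half = optimize.brentq(
            lambda t: m.moles_in_hemisphere(t, self.src, self.tp, geo) / m0 - 0.5, 1e-6, 1e5)
        val = m.recovery_intensity(t_half, self.mapping, self.src, self.tp, geo)
        assert val == pytest.approx(0.5 * (0.2 + 1.0), rel=1e-9)

    def test_invalid_mapping(self):
        with pytest.raises(ValueError):
            gk.BleachMapping(i0=1.0, i_inf=0.5)


class TestBleachSpread:
    tp = gk.TransportParams(d_tissue=32.0)

    def test_zero_duration_unchanged(self):
        assert m.bleach_spread_sigma(300.0, self.tp, 0.0) == 300.0

    def test_correction_small_and_bounded(self):
        eff = m.bleach_spread_sigma(300.0, self.tp, 30.0)
        assert 300.0 <= eff <= np.sqrt(300.0**2 + 2.0 * 32.0 * 30.0)
        assert (eff - 300.0) / 300.0 <= 0.08  # the correction stays below 8 %
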