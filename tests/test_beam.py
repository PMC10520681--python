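"""Unit and property tests for the cantilever mechanics module."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import fixed_quad

from cardiobeam import (
    BeamSpec,
    cell_force,
    cell_layer_strain,
    curvature_from_tip,
    deflection_profile,
    drag_coefficient,
    magnetic_density_from_static_deflection,
    relaxation_time,
    simulate_deflection,
)
from cardiobeam.errors import ModelValidityError, StabilityError


# ---------------------------------------------------------------- BeamSpec

class TestBeamSpec:
    def test_derived_quantities(self, beam):
        assert beam.E_eff == pytest.approx(12e3 / (1 - 0.25))
        assert beam.I == pytest.approx(0.01 * (2e-4) ** 3 / 12)
        assert beam.E_eff > 0 and beam.I > 0

    @pytest.mark.parametrize("field,value", [
        ("L0", -0.01), ("L0", 0.0), ("b", -1.0), ("h", 0.0),
        ("E", -12e3), ("mu", 0.0), ("nu", 1.0), ("nu", -0.1), ("nu", 1.5),
    ])
    def test_invalid_fields_rejected(self, field, value):
        kwargs = dict(L0=0.01, b=0.01, h=2e-4, E=12e3, nu=0.5, mu=1e-3)
        kwargs[field] = value
        with pytest.raises(ValueError):
            BeamSpec(**kwargs)

    def test_nu_half_is_fine(self):
        BeamSpec(L0=0.01, b=0.01, h=2e-4, E=12e3, nu=0.5)

    def test_thick_beam_warns_then_errors(self):
        with pytest.warns(UserWarning, match="thin beam"):
            BeamSpec(L0=0.01, b=0.01, h=2e-3, E=12e3)
        with pytest.raises(ValueError, match="thin-beam"):
            BeamSpec(L0=0.01, b=0.01, h=6e-3, E=12e3)


# ------------------------------------------------------ curvature / profile

class TestKinematics:
    def test_zero_deflection_zero_curvature(self, beam):
        assert curvature_from_tip(0.0, beam) == 0.0

    def test_one_mm_gives_twenty_per_metre(self, beam):
        assert curvature_from_tip(1e-3, beam) == pytest.approx(20.0)

    def test_circle_fit_oracle(self, beam):
        # circumscribed circle through three points of the parabola
        W = 1e-3
        xs = np.array([0.0, beam.L0 / 2, beam.L0])
        ys = deflection_profile(W, beam, xs)
        a = np.hypot(xs[1] - xs[0], ys[1] - ys[0])
        b_ = np.hypot(xs[2] - xs[1], ys[2] - ys[1])
        c_ = np.hypot(xs[2] - xs[0], ys[2] - ys[0])
        area = 0.5 * abs((xs[1] - xs[0]) * (ys[2] - ys[0])
                         - (xs[2] - xs[0]) * (ys[1] - ys[0]))
        curvature_circle = 4 * area / (a * b_ * c_)
        assert curvature_from_tip(W, beam) == pytest.approx(
            curvature_circle, rel=2e-2)

    def test_odd_symmetry(self, beam):
        assert curvature_from_tip(-1e-3, beam) == pytest.approx(-20.0)

    def test_hard_limit_errors(self, beam):
        with pytest.raises(ModelValidityError):
            curvature_from_tip(0.31 * beam.L0, beam)

    def test_soft_limit_warns(self, beam):
        with pytest.warns(UserWarning, match="small-deflection"):
            curvature_from_tip(0.15 * beam.L0, beam)

    def test_profile_endpoints(self, beam):
        assert deflection_profile(1e-3, beam, 0.0) == 0.0
        assert deflection_profile(1e-3, beam, beam.L0) == pytest.approx(1e-3)
        assert deflection_profile(1e-3, beam, beam.L0 / 2) == pytest.approx(0.25e-3)

    def test_profile_domain_error(self, beam):
        with pytest.raises(ValueError):
            deflection_profile(1e-3, beam, -1e-4)
        with pytest.raises(ValueError):
            deflection_profile(1e-3, beam, beam.L0 * 1.01)

    def test_profile_monotone(self, beam):
        x = np.linspace(0, beam.L0, 50)
        w = deflection_profile(1e-3, beam, x)
        assert np.all(np.diff(w) > 0)


class TestStrain:
    def test_zero(self, beam):
        assert cell_layer_strain(0.0, beam) == (0.0, 0.0)

    def test_derived_value(self, beam):
        dL, eps = cell_layer_strain(1e-3, beam)
        assert dL == pytest.approx(20e-6)
        assert eps == pytest.approx(2e-3)

    def test_agrees_with_curvature_route(self, beam):
        # dL = L0 * c * h / 2 must agree exactly
        W = 7.3e-4
        dL, _ = cell_layer_strain(W, beam)
        c = curvature_from_tip(W, beam)
        assert dL == pytest.approx(beam.L0 * c * beam.h / 2, rel=1e-14)

    def test_odd_symmetry(self, beam):
        dL, _ = cell_layer_strain(-0.5e-3, beam)
        assert dL == pytest.approx(-10e-6)


class TestDrag:
    def test_inviscid_limit(self):
        # mu = 0 is rejected by BeamSpec, so check the limit by scaling
        b1 = BeamSpec(L0=0.01, b=0.01, h=2e-4, E=12e3, mu=1e-12)
        assert drag_coefficient(b1) < 1e-11

    def test_derived_value(self, beam):
        assert drag_coefficient(beam) == pytest.approx(3e-3 * np.pi)

    def test_linearity_in_mu(self, beam):
        b2 = BeamSpec(L0=0.01, b=0.01, h=2e-4, E=12e3, mu=2e-3)
        assert drag_coefficient(b2) == pytest.approx(2 * drag_coefficient(beam))


# ------------------------------------------------------------- cell force

def _energy_balance_force(W, Wdot, p_m, beam):
    """Independent oracle: solve the instantaneous power balance for F_cell
    with the three work terms evaluated by Gauss quadrature."""
    c = 2 * W / beam.L0**2
    cdot = 2 * Wdot / beam.L0**2
    lhs = beam.E_eff * beam.I * c * cdot * beam.L0
    k_d = 3 * beam.mu * np.pi * (3 * beam.b + 2 * beam.L0) / (5 * beam.L0)

    def wdot(x):
        return Wdot * x**2 / beam.L0**2

    P_m, _ = fixed_quad(lambda x: p_m * wdot(x), 0, beam.L0, n=20)
    P_d, _ = fixed_quad(lambda x: -k_d * wdot(x) ** 2, 0, beam.L0, n=20)
    Ldot = Wdot * beam.h / beam.L0
    return (P_m + P_d - lhs) / Ldot


class TestCellForce:
    def test_all_zero(self, beam):
        assert cell_force(0.0, 0.0, 0.0, beam) == 0.0

    def test_static_upward_deflection(self, beam):
        # upward bend with no load is held by cell tension
        F = cell_force(-1e-3, 0.0, 0.0, beam)
        assert F == pytest.approx(2.1333333e-5, rel=1e-6)

    def test_symbolic_energy_oracle(self, beam):
        W_, Wd_, pm_, F_, x_ = sp.symbols("W Wd pm F x")
        L0_, b_, h_, E_, nu_, mu_ = sp.symbols("L0 b h E nu mu", positive=True)
        Ebar = E_ / (1 - nu_**2)
        I_ = b_ * h_**3 / 12
        c = 2 * W_ / L0_**2
        cdot = 2 * Wd_ / L0_**2
        wdot = Wd_ * x_**2 / L0_**2
        kd = 3 * mu_ * sp.pi * (3 * b_ + 2 * L0_) / (5 * L0_)
        lhs = Ebar * I_ * c * cdot * L0_
        rhs = (sp.integrate(pm_ * wdot, (x_, 0, L0_))
               + sp.integrate(-kd * wdot * wdot, (x_, 0, L0_))
               - F_ * Wd_ * h_ / L0_)
        F_sym = sp.solve(sp.Eq(lhs, rhs), F_)[0]
        f = sp.lambdify((W_, Wd_, pm_, L0_, b_, h_, E_, nu_, mu_), F_sym, "numpy")
        rng = np.random.default_rng(0)
        for _ in range(20):
            W = rng.uniform(-2e-3, 2e-3)
            Wd = rng.uniform(-0.05, 0.05)
            while abs(Wd) < 1e-4:
                Wd = rng.uniform(-0.05, 0.05)
            pm = rng.uniform(0, 2e-4)
            expected = f(W, Wd, pm, beam.L0, beam.b, beam.h, beam.E, beam.nu, beam.mu)
            assert cell_force(W, Wd, pm, beam) == pytest.approx(expected, rel=1e-12)

    def test_quadrature_oracle_random_states(self, rng):
        for _ in range(100):
            beam = BeamSpec(
                L0=rng.uniform(5e-3, 2e-2), b=rng.uniform(5e-3, 2e-2),
                h=rng.uniform(1e-4, 4e-4), E=rng.uniform(5e3, 3e4),
                nu=rng.uniform(0.0, 0.5), mu=rng.uniform(5e-4, 5e-3))
            W = rng.uniform(-0.05, 0.05) * beam.L0
            Wd = rng.choice([-1, 1]) * rng.uniform(1e-4, 0.05)
            pm = rng.uniform(0, 2e-4)
            got = cell_force(W, Wd, pm, beam)
            want = _energy_balance_force(W, Wd, pm, beam)
            assert got == pytest.approx(want, rel=1e-10)

    def test_nonfinite_rejected(self, beam):
        with pytest.raises(ValueError):
            cell_force(np.nan, 0.0, 0.0, beam)
        with pytest.raises(ValueError):
            cell_force(0.0, 0.0, np.inf, beam)

    @given(a=st.floats(-2, 2), b_=st.floats(-2, 2))
    @settings(max_examples=30, deadline=None)
    def test_linearity_in_each_argument(self, a, b_):
        beam = BeamSpec(L0=0.01, b=0.01, h=2e-4, E=12e3, nu=0.5, mu=1e-3)
        W0, Wd0, pm0 = 4e-4, 0.01, 5e-5
        base = cell_force(0.0, 0.0, 0.0, beam)
        for args in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            fa = cell_force(a * W0 * args[0], a * Wd0 * args[1], a * pm0 * args[2], beam)
            fb = cell_force(b_ * W0 * args[0], b_ * Wd0 * args[1], b_ * pm0 * args[2], beam)
            fab = cell_force((a + b_) * W0 * args[0], (a + b_) * Wd0 * args[1],
                             (a + b_) * pm0 * args[2], beam)
            assert fab - base == pytest.approx((fa - base) + (fb - base), abs=1e-16)


# ------------------------------------------------------------- calibration

class TestStaticCalibration:
    def test_zero(self, beam):
        for mode in ("energy_consistent", "paper_eq4"):
            assert magnetic_density_from_static_deflection(0.0, beam, mode) == 0.0

    def test_derived_values(self, beam):
        ec = magnetic_density_from_static_deflection(1e-3, beam, "energy_consistent")
        eq4 = magnetic_density_from_static_deflection(1e-3, beam, "paper_eq4")
        assert ec == pytest.approx(1.28e-4, rel=1e-6)
        assert eq4 == pytest.approx(8.5333333e-5, rel=1e-6)

    def test_mode_ratio_is_two_thirds(self, rng):
        for _ in range(50):
            beam = BeamSpec(
                L0=rng.uniform(5e-3, 2e-2), b=rng.uniform(5e-3, 2e-2),
                h=rng.uniform(1e-4, 4e-4), E=rng.uniform(5e3, 3e4),
                nu=rng.uniform(0.0, 0.5))
            W_m = rng.uniform(1e-5, 1e-3)
            ec = magnetic_density_from_static_deflection(W_m, beam, "energy_consistent")
            eq4 = magnetic_density_from_static_deflection(W_m, beam, "paper_eq4")
            assert eq4 / ec == pytest.approx(2.0 / 3.0, rel=1e-14)

    def test_energy_consistent_inverts_to_zero_force(self, beam):
        W_m = 8e-4
        pm = magnetic_density_from_static_deflection(W_m, beam, "energy_consistent")
        assert abs(cell_force(W_m, 0.0, pm, beam)) < 1e-12

    def test_paper_eq4_static_bias(self, beam):
        # documented inconsistency: eq4 calibration leaves a residual force
        W_m = 8e-4
        pm = magnetic_density_from_static_deflection(W_m, beam, "paper_eq4")
        bias = -beam.E_eff * beam.b * beam.h**2 * W_m / (9 * beam.L0**2)
        assert cell_force(W_m, 0.0, pm, beam) == pytest.approx(bias, rel=1e-12)

    def test_unknown_mode(self, beam):
        with pytest.raises(ValueError):
            magnetic_density_from_static_deflection(1e-3, beam, "bogus")


# ----------------------------------------------------------------- dynamics

class TestDynamics:
    def test_relaxation_time_value(self, beam):
        assert relaxation_time(beam) == pytest.approx(44.18e-3, rel=1e-3)

    def test_relaxation_scalings(self, beam):
        b_mu = BeamSpec(L0=0.01, b=0.01, h=2e-4, E=12e3, mu=2e-3)
        assert relaxation_time(b_mu) == pytest.approx(2 * relaxation_time(beam))
        b_E = BeamSpec(L0=0.01, b=0.01, h=2e-4, E=24e3)
        assert relaxation_time(b_E) == pytest.approx(relaxation_time(beam) / 2)
        b_tiny = BeamSpec(L0=0.01, b=0.01, h=2e-4, E=12e3, mu=1e-9)
        assert relaxation_time(b_tiny) < 1e-7

    def test_quiescent(self, beam):
        tr = simulate_deflection(np.zeros(100), np.zeros(100), beam, W0=0.0, dt=1e-3)
        assert np.all(tr.W == 0.0)
        assert np.all(tr.Wdot == 0.0)

    def test_step_release_matches_exponential(self, beam):
        tau = relaxation_time(beam)
        dt = tau / 50
        n = int(5 * tau / dt)
        tr = simulate_deflection(np.zeros(n), np.zeros(n), beam, W0=1e-3, dt=dt)
        expected = 1e-3 * np.exp(-tr.t / tau)
        assert np.max(np.abs(tr.W - expected)) < 1e-3 * 1e-3  # <0.1 % of W0

    def test_round_trip(self, beam, twitch_model):
        from cardiobeam import twitch_waveform
        dt = 2e-3
        t = np.arange(0, 4.0, dt)
        F = np.zeros_like(t)
        for ts in (0.5, 2.5):
            m = t >= ts
            F[m] += twitch_waveform(twitch_model, 1e-3, t[m] - ts)
        pm = np.where(np.mod(t, 2.0) < 0.5, 3e-5, 0.0)
        tr = simulate_deflection(F, pm, beam, W0=0.0, dt=dt)
        F_rec = cell_force(tr.W, tr.Wdot, pm, beam)
        peak = np.max(np.abs(F))
        assert np.max(np.abs(F_rec - F)) / peak < 1e-9

    def test_dt_too_coarse(self, beam):
        tau = relaxation_time(beam)
        with pytest.raises(StabilityError):
            simulate_deflection(np.zeros(10), np.zeros(10), beam, dt=tau)

    def test_bad_inputs(self, beam):
        with pytest.raises(StabilityError):
            simulate_deflection(np.zeros(10), np.zeros(10), beam, dt=-1.0)
        with pytest.raises(ValueError):
            simulate_deflection(np.zeros(10), np.zeros(7), beam, dt=1e-3)

    def test_overdeflection_raises(self, beam):
        with pytest.raises(ModelValidityError):
            simulate_deflection(np.zeros(5000), np.full(5000, 5e-3), beam,
                                W0=0.0, dt=1e-3)
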