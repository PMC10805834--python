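"""Closed-form kinetics against independent ODE/quadrature oracles and the
linearity properties of the superposition solution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

from ilapop.structural import (ConcentrationProfile, DoseEvent, PKParameters,
                               auc_exact, auc_trapezoid, concentration_1cmt,
                               concentration_2cmt, exposure_metrics,
                               macro_constants)


def _ode_piecewise(rhs_for_rate, regimen, times, n_states):
    """Integrate segment-by-segment between infusion on/off switches, so the
    solver never steps across a discontinuity and can run at tight
    tolerance without a max_step crutch."""
    t_end = float(max(times))
    edges = sorted({0.0, t_end,
                    *[e.start_time for e in regimen if e.start_time < t_end],
                    *[e.end_time for e in regimen if e.end_time < t_end]})
    times = np.asarray(times, float)
    out = np.empty((n_states, times.size))
    y = np.zeros(n_states)
    for lo, hi in zip(edges[:-1], edges[1:]):
        rate = sum(e.rate_ug_per_h for e in regimen
                   if e.start_time <= lo and hi <= e.end_time)
        sel = (times > lo) & (times <= hi)
        t_eval = np.unique(np.append(times[sel], hi))
        sol = solve_ivp(rhs_for_rate(rate), [lo, hi], y, t_eval=t_eval,
                        method="LSODA", rtol=1e-12, atol=1e-12)
        idx = np.searchsorted(t_eval, times[sel])
        out[:, sel] = sol.y[:, idx]
        y = sol.y[:, -1]
    out[:, times <= edges[0]] = 0.0
    return out


def ode_profile_2cmt(params, regimen, times):
    """Stiff ODE integration of the two-compartment system (oracle)."""
    V, Vp, CL, CLp = params.V, params.Vp, params.CL, params.CLp

    def rhs_for_rate(rate):
        def rhs(t, y):
            a1, a2 = y
            return [rate - (CL + CLp) / V * a1 + CLp / Vp * a2,
                    CLp / V * a1 - CLp / Vp * a2]
        return rhs

    return _ode_piecewise(rhs_for_rate, regimen, times, 2)[0] / V


def ode_profile_1cmt(V, CL, regimen, times):
    def rhs_for_rate(rate):
        def rhs(t, y):
            return [rate - CL / V * y[0]]
        return rhs

    return _ode_piecewise(rhs_for_rate, regimen, times, 1)[0] / V


class TestMacroConstants:
    def test_eigenvalue_oracle(self, typical_params):
        """alpha/beta equal the eigenvalue magnitudes of the rate matrix."""
        p = typical_params
        A = np.array([[-(p.k10 + p.k12), p.k21], [p.k12, -p.k21]])
        lam = np.sort(-np.linalg.eigvals(A))          # [beta, alpha]
        alpha, beta = macro_constants(p)
        assert alpha == pytest.approx(lam[1], rel=1e-12)
        assert beta == pytest.approx(lam[0], rel=1e-12)

    def test_sum_and_product_identities(self, typical_params):
        p = typical_params
        alpha, beta = macro_constants(p)
        assert alpha + beta == pytest.approx(p.k10 + p.k12 + p.k21, rel=1e-12)
        assert alpha * beta == pytest.approx(p.k10 * p.k21, rel=1e-12)
        assert alpha >= beta > 0

    def test_large_vp_limit(self):
        """As Vp -> inf (k21 -> 0): beta -> 0 and alpha -> k10 + k12."""
        p = PKParameters(V=6.795, Vp=1e9, CL=3.394, CLp=13.086)
        alpha, beta = macro_constants(p)
        assert beta < 1e-7
        assert alpha == pytest.approx(p.k10 + p.k12, rel=1e-6)

    @pytest.mark.parametrize("bad", [
        dict(V=0.0, Vp=5.0, CL=3.0, CLp=13.0),
        dict(V=6.0, Vp=-1.0, CL=3.0, CLp=13.0),
        dict(V=6.0, Vp=5.0, CL=0.0, CLp=13.0),
    ])
    def test_nonpositive_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            PKParameters(**bad)


SINGLE_20 = [DoseEvent(20.0, 0.0, 0.75)]
LOADING = [DoseEvent(20.0, 0.0, 0.75), DoseEvent(10.0, 24.0, 0.75),
           DoseEvent(10.0, 48.0, 0.75)]


class TestConcentration2cmt:
    def test_empty_regimen_is_zero(self):
        p = PKParameters(6.795, 5.544, 3.394, 13.086)
        prof = concentration_2cmt(p, [], np.linspace(0, 24, 10))
        assert np.all(prof.concentrations == 0)

    def test_zero_before_first_dose(self, typical_params):
        reg = [DoseEvent(20.0, 5.0, 0.75)]
        prof = concentration_2cmt(typical_params, reg, [0.0, 1.0, 4.9, 5.5])
        assert np.all(prof.concentrations[:3] == 0)
        assert prof.concentrations[3] > 0

    def test_negative_time_rejected(self, typical_params):
        with pytest.raises(ValueError):
            concentration_2cmt(typical_params, SINGLE_20, [-1.0, 2.0])

    @pytest.mark.parametrize("regimen", [SINGLE_20, LOADING],
                             ids=["single-20mg", "loading-20-10-10"])
    def test_matches_ode_oracle(self, typical_params, regimen):
        t_end = 24.0 if len(regimen) == 1 else 72.0
        times = np.linspace(0.05, t_end, 50)
        closed = concentration_2cmt(typical_params, regimen, times).concentrations
        ode = ode_profile_2cmt(typical_params, regimen, times)
        assert np.max(np.abs(closed - ode) / np.abs(ode)) < 1e-6

    def test_continuous_at_infusion_end(self, typical_params):
        eps = 1e-9
        t = [0.75 - eps, 0.75, 0.75 + eps]
        c = concentration_2cmt(typical_params, SINGLE_20, t).concentrations
        assert c[0] == pytest.approx(c[1], rel=1e-6)
        assert c[2] == pytest.approx(c[1], rel=1e-6)


class TestConcentration1cmt:
    def test_empty_regimen_and_oracle(self):
        assert np.all(concentration_1cmt((10.0, 3.0), [],
                                         [0, 1, 2]).concentrations == 0)
        times = np.linspace(0.05, 24, 50)
        closed = concentration_1cmt((10.0, 3.0), SINGLE_20, times).concentrations
        ode = ode_profile_1cmt(10.0, 3.0, SINGLE_20, times)
        assert np.max(np.abs(closed - ode) / np.abs(ode)) < 1e-6

    def test_postinfusion_log_slope_is_minus_k(self):
        V, CL = 8.0, 2.5
        t = np.array([2.0, 6.0, 12.0, 20.0])
        c = concentration_1cmt((V, CL), SINGLE_20, t).concentrations
        slopes = np.diff(np.log(c)) / np.diff(t)
        assert np.allclose(slopes, -CL / V, rtol=1e-10)


def random_params(rng) -> PKParameters:
    return PKParameters(V=float(rng.uniform(2, 40)),
                        Vp=float(rng.uniform(2, 60)),
                        CL=float(rng.uniform(0.5, 15)),
                        CLp=float(rng.uniform(0.5, 30)))


class TestProperties:
    def test_superposition_linearity(self, typical_params):
        regA = [DoseEvent(20.0, 0.0, 0.75)]
        regB = [DoseEvent(10.0, 24.0, 0.75), DoseEvent(10.0, 48.0, 0.75)]
        t = np.linspace(0.1, 72, 200)
        cA = concentration_2cmt(typical_params, regA, t).concentrations
        cB = concentration_2cmt(typical_params, regB, t).concentrations
        cAB = concentration_2cmt(typical_params, regA + regB, t).concentrations
        ok = cAB > 0
        assert np.max(np.abs((cA + cB - cAB))[ok] / cAB[ok]) < 1e-10

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_dose_proportionality(self, scale):
        p = PKParameters(6.795, 5.544, 3.394, 13.086)
        t = np.linspace(0.1, 24, 40)
        base = concentration_2cmt(p, SINGLE_20, t).concentrations
        scaled_reg = [DoseEvent(20.0 * scale, 0.0, 0.75)]
        scaled = concentration_2cmt(p, scaled_reg, t).concentrations
        assert np.allclose(scaled, scale * base, rtol=1e-10)
        assert auc_exact(p, scaled_reg, 24.0) == pytest.approx(
            scale * auc_exact(p, SINGLE_20, 24.0), rel=1e-10)

    def test_reduces_to_one_compartment_as_clp_vanishes(self):
        """Pointwise convergence; the error scales roughly with CLp (the
        terminal tail always ends in the slow beta phase, so convergence is
        not uniform in time)."""
        t = np.linspace(0.1, 24, 50)
        one = concentration_1cmt((6.795, 3.394), SINGLE_20, t).concentrations
        for clp, tol in [(1e-3, 2e-2), (1e-6, 2e-5)]:
            p = PKParameters(6.795, 5.544, 3.394, clp)
            two = concentration_2cmt(p, SINGLE_20, t).concentrations
            assert np.max(np.abs(two - one) / one) < tol

    def test_random_draws_match_ode(self):
        """Closed form vs stiff ODE over random parameter/regimen draws."""
        rng = np.random.default_rng(202)
        for _ in range(25):
            p = random_params(rng)
            dur = float(rng.uniform(0.25, 2.0))
            reg = [DoseEvent(float(rng.uniform(5, 30)), 0.0, dur)]
            if rng.random() < 0.5:
                reg.append(DoseEvent(float(rng.uniform(5, 30)),
                                     float(rng.uniform(dur + 0.5, 24)), dur))
            t_end = max(e.end_time for e in reg) + 24.0
            times = np.linspace(0.05, t_end, 30)
            closed = concentration_2cmt(p, reg, times).concentrations
            ode = ode_profile_2cmt(p, reg, times)
            keep = ode > 1e-9 * ode.max()   # below this the ODE tolerance,
            # not the closed form, limits the relative comparison
            err = np.abs(closed - ode)[keep] / ode[keep]
            assert np.max(err) < 1e-6


class TestExposureMetrics:
    def test_auc_inf_is_dose_over_clearance(self, typical_params):
        m = exposure_metrics(typical_params, SINGLE_20, t_end=24.0)
        assert m.AUC_0_inf == pytest.approx(20000.0 / 3.394, rel=1e-12)

    def test_truncated_auc_monotone_to_auc_inf(self, typical_params):
        aucs = [auc_exact(typical_params, SINGLE_20, t) for t in (24, 48, 96, 400)]
        assert all(np.diff(aucs) > 0)
        assert aucs[-1] == pytest.approx(20000.0 / 3.394, rel=1e-6)
        assert aucs[0] < 20000.0 / 3.394

    def test_auc_exact_matches_quadrature(self, typical_params):
        """Piecewise-analytic AUC vs adaptive quadrature of the closed form."""
        def c(t):
            return concentration_2cmt(typical_params, SINGLE_20,
                                      [t]).concentrations[0]
        num, _ = quad(c, 0, 24, points=[0.75], limit=200, epsabs=1e-10,
                      epsrel=1e-12)
        assert auc_exact(typical_params, SINGLE_20, 24.0) == \
            pytest.approx(num, rel=1e-9)

    def test_trapezoid_close_but_distinct(self, typical_params):
        sched = np.array([0.25, 0.5, 0.75, 5 / 6, 1, 1.5, 2, 3, 4, 5, 8, 12, 24])
        tz = auc_trapezoid(typical_params, SINGLE_20, sched)
        ex = auc_exact(typical_params, SINGLE_20, 24.0)
        assert abs(tz - ex) / ex < 0.05
        assert tz != ex

    def test_cmax_at_infusion_end_single_dose(self, typical_params):
        m = exposure_metrics(typical_params, SINGLE_20, t_end=24.0)
        assert m.Tmax == pytest.approx(0.75, abs=1e-9)
        c_end = concentration_2cmt(typical_params, SINGLE_20,
                                   [0.75]).concentrations[0]
        assert m.Cmax == pytest.approx(c_end, rel=1e-12)

    def test_t_end_before_infusion_end_rejected(self, typical_params):
        with pytest.raises(ValueError):
            exposure_metrics(typical_params, SINGLE_20, t_end=0.5)

    def test_profile_shape_validation(self):
        with pytest.raises(ValueError):
            ConcentrationProfile(np.array([0.0, 1.0]), np.array([0.0]))
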