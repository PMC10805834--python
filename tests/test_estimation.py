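"""FOCE-ELS estimation: likelihood-level oracles (closed-form Gaussian,
adaptive quadrature), degenerate limits, invariances and fit behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from conftest import tiny_dataset
from ilapop.data import PopPKDataset, builtin_designs, simulate_trial
from ilapop.estimation import (CovariateEffect, PopPKModel, compare_models,
                               eta_shrinkage, lrt_threshold,
                               subject_objective)


class TestLrtThreshold:
    def test_published_thresholds(self):
        assert lrt_threshold(0.01, 1) == pytest.approx(6.635, abs=5e-4)
        assert lrt_threshold(0.001, 1) == pytest.approx(10.828, abs=5e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lrt_threshold(0.0, 1)
        with pytest.raises(ValueError):
            lrt_threshold(0.05, 0)


class TestSubjectObjective:
    def test_matches_hand_written_gaussian(self):
        """The conditional objective is the -2 log joint density: residual
        term with multiplicative variance plus the eta prior."""
        ds = tiny_dataset(n_subjects=1, seed=5)
        m = PopPKModel(ds, iiv=("CL",))
        vals = dict(tv_V=6.795, tv_Vp=5.544, tv_CL=3.394, tv_CLp=13.086,
                    omega2_CL=0.09, sigma_mult=0.15)
        eta = np.array([0.21])

        from ilapop.structural import DoseEvent, PKParameters, concentration_2cmt
        p = PKParameters(6.795, 5.544, 3.394 * np.exp(0.21), 13.086)
        f = concentration_2cmt(p, [DoseEvent(20.0, 0.0, 0.75)],
                               [1.0, 4.0, 12.0]).concentrations
        y = ds.frame[ds.frame.EVID == 0].DV.to_numpy()
        v = (0.15 * f) ** 2
        expected = float(np.sum((y - f) ** 2 / v + np.log(v)
                                + np.log(2 * np.pi))
                         + 0.21 ** 2 / 0.09 + np.log(0.09) + np.log(2 * np.pi))
        got = subject_objective(m, 1, vals, eta)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_zero_eta_has_no_quadratic_penalty(self):
        """At eta = 0 only the prior normalising constant log|Omega| changes
        with omega^2 — the quadratic penalty eta'Omega^-1 eta is zero."""
        ds = tiny_dataset(n_subjects=1, seed=5)
        m = PopPKModel(ds, iiv=("CL",))
        vals = dict(tv_V=6.795, tv_Vp=5.544, tv_CL=3.394, tv_CLp=13.086,
                    sigma_mult=0.15)
        a = subject_objective(m, 1, dict(vals, omega2_CL=0.04), np.zeros(1))
        b = subject_objective(m, 1, dict(vals, omega2_CL=4.0), np.zeros(1))
        assert b - a == pytest.approx(np.log(4.0 / 0.04), rel=1e-10)
        # at fixed nonzero eta the omega-difference picks up the quadratic
        # term as well (the residual part cancels)
        a2 = subject_objective(m, 1, dict(vals, omega2_CL=0.04),
                               np.array([0.3]))
        b2 = subject_objective(m, 1, dict(vals, omega2_CL=4.0),
                               np.array([0.3]))
        expected = np.log(4.0 / 0.04) + 0.3 ** 2 * (1 / 4.0 - 1 / 0.04)
        assert b2 - a2 == pytest.approx(expected, rel=1e-10)


class TestFoceOfv:
    def test_exact_for_linear_model_with_additive_error(self):
        """FOCE-ELS equals the closed-form Gaussian marginal -2LL when the
        model is linear in eta with additive error (Laplace is exact)."""
        rng = np.random.default_rng(7)
        N, T = 4, 5
        B = rng.normal(0, 1.5, size=(T, 2))
        a = rng.normal(10, 2, size=T)
        rows, Y = [], np.empty((N, T))
        for i in range(N):
            eta = rng.normal(0, [0.4, 0.7])
            Y[i] = a + B @ eta + rng.normal(0, 0.3, T)
            rows.append(dict(ID=i + 1, TIME=0.0, AMT=1.0, DUR=0.5, DV=0.0,
                             EVID=1, MDV=1, BLQ=0, SEX=0, DIS=0, AGE=25.0,
                             HT=168.0, WT=60.0, SCR=0.8))
            for j in range(T):
                rows.append(dict(ID=i + 1, TIME=float(j + 1), AMT=0.0,
                                 DUR=0.0, DV=Y[i, j], EVID=0, MDV=0, BLQ=0,
                                 SEX=0, DIS=0, AGE=25.0, HT=168.0, WT=60.0,
                                 SCR=0.8))
        ds = PopPKDataset(pd.DataFrame(rows))

        class LinearInEta(PopPKModel):
            def _f_eta(self, logbase, eta):
                return a[None, :] + eta @ B.T

            def _f_eta_multi(self, logbase, stack):
                return a[None, None, :] + stack @ B.T

        m = LinearInEta(ds, structural="one_compartment", iiv=("V", "CL"),
                        residual="additive")
        vals = dict(tv_V=10.0, tv_CL=5.0, omega2_V=0.16, omega2_CL=0.49,
                    sigma_add=0.3)
        ofv = m.ofv(vals)
        Sigma = B @ np.diag([0.16, 0.49]) @ B.T + 0.09 * np.eye(T)
        exact = sum(-2 * stats.multivariate_normal.logpdf(Y[i], a, Sigma)
                    for i in range(N))
        assert abs(ofv - exact) < 1e-4

    def test_close_to_adaptive_quadrature_on_tiny_instance(self):
        """2 subjects, 1 eta, 3 observations: the FOCE approximation tracks
        the exact marginal computed by adaptive quadrature."""
        ds = tiny_dataset(n_subjects=2, seed=3)
        m = PopPKModel(ds, iiv=("CL",))
        vals = dict(tv_V=6.795, tv_Vp=5.544, tv_CL=3.394, tv_CLp=13.086,
                    omega2_CL=0.0625, sigma_mult=0.15)
        ofv = m.ofv(vals)

        b = m._batch
        logbase = m._log_base(vals)

        def minus2ll(i):
            def integrand(eta):
                full = np.zeros((m._n, 1))
                full[i, 0] = eta
                f = m._f_eta(logbase, full)[i][b["obs_mask"][i]]
                y = b["y"][i][b["obs_mask"][i]]
                v = (0.15 * f) ** 2
                ll = -0.5 * np.sum((y - f) ** 2 / v + np.log(2 * np.pi * v))
                return np.exp(ll) * stats.norm.pdf(eta, 0, 0.25)
            val, _ = integrate.quad(integrand, -2.0, 2.0, limit=200,
                                    epsabs=1e-13, epsrel=1e-11)
            return -2.0 * np.log(val)

        exact = minus2ll(0) + minus2ll(1)
        assert abs(ofv - exact) < 0.3

    def test_vanishing_iiv_reduces_to_pooled_els(self):
        ds = tiny_dataset(n_subjects=3, seed=9)
        vals = dict(tv_V=6.795, tv_Vp=5.544, tv_CL=3.394, tv_CLp=13.086,
                    sigma_mult=0.2)
        pooled = PopPKModel(ds, iiv=()).ofv(vals)
        shrunk = PopPKModel(ds, iiv=("CL",),
                            fixed_omega2={"CL": 1e-12}).ofv(vals)
        assert shrunk == pytest.approx(pooled, abs=1e-5)

    def test_invariant_to_subject_order(self):
        ds = tiny_dataset(n_subjects=3, seed=11)
        vals = dict(tv_V=6.795, tv_Vp=5.544, tv_CL=3.394, tv_CLp=13.086,
                    omega2_V=0.013, omega2_Vp=0.032, omega2_CL=0.059,
                    sigma_mult=0.184)
        ofv = PopPKModel(ds).ofv(vals)
        shuffled = PopPKDataset(
            pd.concat([ds.frame[ds.frame.ID == i] for i in (2, 3, 1)],
                      ignore_index=True))
        assert PopPKModel(shuffled).ofv(vals) == pytest.approx(ofv, abs=1e-8)

    def test_invariant_to_time_shift_of_whole_subject(self):
        ds = tiny_dataset(n_subjects=3, seed=11)
        vals = dict(tv_V=6.795, tv_Vp=5.544, tv_CL=3.394, tv_CLp=13.086,
                    omega2_V=0.013, omega2_Vp=0.032, omega2_CL=0.059,
                    sigma_mult=0.184)
        ofv = PopPKModel(ds).ofv(vals)
        f = ds.frame.copy()
        f.loc[f.ID == 2, "TIME"] += 100.0     # doses and samples together
        assert PopPKModel(PopPKDataset(f)).ofv(vals) == \
            pytest.approx(ofv, abs=1e-8)


class TestFit:
    def test_fit_improves_on_start_and_reports_metrics(self, base_fit):
        model = base_fit.model
        start_ofv = model.ofv(base_fit.start, update_cache=False)
        assert base_fit.ofv <= start_ofv
        assert base_fit.converged
        assert base_fit.aic == pytest.approx(base_fit.ofv + 2 * model.k_params)
        assert base_fit.bic == pytest.approx(
            base_fit.ofv + model.k_params * np.log(base_fit.n_obs))
        assert set(base_fit.params) == set(model.param_names)

    def test_refit_from_optimum_stays_there(self, base_fit, high_dose_dataset):
        m = PopPKModel(high_dose_dataset)
        again = m.fit(start=base_fit.params, preset="fast", compute_se=False)
        assert again.ofv == pytest.approx(base_fit.ofv, abs=0.05)

    def test_summary_and_report(self, base_fit):
        text = base_fit.summary()
        assert "OFV" in text and "tv_V" in text
        report = base_fit.to_dict()
        assert report["n_subjects"] == 10
        import json
        json.dumps(report)                     # serialisable
        assert "OFV" in base_fit.run_log()

    def test_evaluate_matches_ofv(self, high_dose_dataset, truth_values):
        m = PopPKModel(high_dose_dataset)
        vals = {k: v for k, v in truth_values.items()
                if k in m.param_names}
        res = m.evaluate(vals)
        assert res.ofv == pytest.approx(m.ofv(vals, update_cache=False),
                                        abs=1e-6)
        assert res.ebes.shape == (10, 3)


class TestPredictionKernel:
    def test_fast_kernel_matches_public_closed_form(self, truth):
        """The jitted masked kernel used by the estimation engine agrees
        with the public closed-form evaluator on every observation cell."""
        from ilapop.structural import DoseEvent, PKParameters, concentration_2cmt

        ds = simulate_trial(builtin_designs()["loading_dose"], truth, seed=13)
        m = PopPKModel(ds)
        rng = np.random.default_rng(0)
        eta = rng.normal(0, 0.2, size=(m._n, 3))
        vals = dict(tv_V=6.795, tv_Vp=5.544, tv_CL=3.394, tv_CLp=13.086,
                    omega2_V=0.013, omega2_Vp=0.032, omega2_CL=0.059,
                    sigma_mult=0.184)
        f = m._f_eta(m._log_base(vals), eta)
        b = m._batch
        regimen = [DoseEvent(20.0, 0.0, 0.75), DoseEvent(10.0, 24.0, 0.75),
                   DoseEvent(10.0, 48.0, 0.75)]
        for i in range(m._n):
            p = PKParameters(V=6.795 * np.exp(eta[i, 0]),
                             Vp=5.544 * np.exp(eta[i, 1]),
                             CL=3.394 * np.exp(eta[i, 2]),
                             CLp=13.086)
            mask = b["obs_mask"][i]
            ref = concentration_2cmt(p, regimen,
                                     b["times"][i][mask]).concentrations
            assert np.allclose(f[i][mask], ref, rtol=1e-9, atol=1e-9)


class TestShrinkage:
    def test_degenerate_cases(self):
        ebes = np.zeros((50, 2))
        out = eta_shrinkage(ebes, np.array([0.04, 0.0]))
        assert out[0] == pytest.approx(100.0)
        assert np.isnan(out[1])

    def test_well_dispersed_ebes_have_low_shrinkage(self):
        rng = np.random.default_rng(0)
        ebes = rng.normal(0, 0.2, size=(4000, 1))
        out = eta_shrinkage(ebes, np.array([0.04]))
        assert abs(out[0]) < 5.0

    def test_sparse_sampling_shrinks_more_than_rich(self, truth):
        """1 observation/subject collapses the EBEs toward zero relative to
        the 14-sample design (both evaluated at the generating truth)."""
        design = builtin_designs()["high_dose"]
        ds_rich = simulate_trial(design, truth, seed=21)
        sparse_frame = ds_rich.frame[
            (ds_rich.frame.EVID == 1)
            | (ds_rich.frame.TIME == 12.0)].reset_index(drop=True)
        ds_sparse = PopPKDataset(sparse_frame)
        vals = dict(tv_V=6.795, tv_Vp=5.544, tv_CL=3.394, tv_CLp=13.086,
                    omega2_V=0.013, omega2_Vp=0.032, omega2_CL=0.059,
                    sigma_mult=0.184)
        rich = PopPKModel(ds_rich).evaluate(vals)
        sparse = PopPKModel(ds_sparse).evaluate(vals)
        assert sparse.shrinkage["CL"] > rich.shrinkage["CL"] + 10.0

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            eta_shrinkage(np.zeros((1, 2)), np.array([0.1, 0.1]))


class TestCompare:
    def test_identical_fits_compare_to_zero(self, base_fit):
        assert compare_models(base_fit, base_fit) == (0.0, 0.0, 0.0)

    def test_different_datasets_rejected(self, base_fit, mixed_dataset):
        other = PopPKModel(mixed_dataset).evaluate(
            dict(tv_V=6.795, tv_Vp=5.544, tv_CL=3.394, tv_CLp=13.086,
                 omega2_V=0.013, omega2_Vp=0.032, omega2_CL=0.059,
                 sigma_mult=0.184))
        with pytest.raises(ValueError):
            compare_models(base_fit, other)


class TestModelSpecValidation:
    def test_unknown_structural_and_residual(self, high_dose_dataset):
        with pytest.raises(ValueError):
            PopPKModel(high_dose_dataset, structural="three_compartment")
        with pytest.raises(ValueError):
            PopPKModel(high_dose_dataset, residual="cauchy")

    def test_effect_must_reference_existing_column(self, high_dose_dataset):
        with pytest.raises(ValueError):
            PopPKModel(high_dose_dataset,
                       covariate_effects=[CovariateEffect("CL", "EGFR")])
        with pytest.raises(ValueError):
            PopPKModel(high_dose_dataset,
                       covariate_effects=[CovariateEffect("Q3", "WT")])

    def test_continuous_reference_is_dataset_median(self, mixed_dataset):
        m = PopPKModel(mixed_dataset,
                       covariate_effects=[CovariateEffect("Vp", "WT")])
        wt = mixed_dataset.covariate_table()["WT"]
        assert m._effect_refs["WT_Vp"] == pytest.approx(float(wt.median()))
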