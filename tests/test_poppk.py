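"""Population model structure, likelihood approximations, and estimation."""

import math

import numpy as np
import pandas as pd
import pytest

from meropk import (ClearancePartition, EstimationError, FixedParams,
                    cl_decay_from_invitro, fit_poppk, gof_tables,
                    individual_clearance, neg2ll, partition_clearance,
                    predict_css)
from meropk.poppk import PopPKDataset, _Design, empirical_bayes, neg2ll_bruteforce
from meropk.synthetic_data import CohortSpec, gen_cohort


class TestStructuralModel:
    def test_individual_clearance_components_add(self):
        fx = FixedParams(cl_decay=0.66)
        assert individual_clearance(fx, 3.6, 139.0, 0.0) == pytest.approx(12.60)

    def test_units_factor_only(self):
        fx = FixedParams(cl_decay=0.0)
        assert individual_clearance(fx, 0.0, 100.0, 0.0) == pytest.approx(6.0)

    def test_eta_is_exponential(self):
        fx = FixedParams()
        base = individual_clearance(fx, 3.6, 139.0, 0.0)
        assert individual_clearance(fx, 3.6, 139.0, math.log(2)) == \
            pytest.approx(2.0 * base)

    def test_rejects_bad_inputs(self):
        fx = FixedParams()
        with pytest.raises(ValueError):
            individual_clearance(fx, 3.6, -1.0, 0.0)
        with pytest.raises(ValueError):
            individual_clearance(fx, 3.6, 100.0, float("nan"))

    def test_css_at_median_infusion_rate(self):
        assert predict_css(250.0, 11.4) == pytest.approx(21.93, abs=0.005)
        assert predict_css(0.0, 5.0) == 0.0
        assert predict_css(250.0, 2 * 11.4) == pytest.approx(21.93 / 2, abs=0.01)
        with pytest.raises(ValueError):
            predict_css(250.0, 0.0)

    def test_steady_state_mass_balance(self):
        """Css * CL returns the infusion rate exactly."""
        for rate, cl in [(250.0, 11.4), (125.0, 5.2), (176.3, 25.3)]:
            assert predict_css(rate, cl) * cl == pytest.approx(rate, rel=1e-14)

    def test_cl_decay_bridge(self):
        assert cl_decay_from_invitro(0.025, 26.2) == pytest.approx(0.655)
        assert cl_decay_from_invitro(0.0, 26.2) == 0.0
        assert cl_decay_from_invitro(0.006, 26.2) == pytest.approx(0.157, abs=5e-4)


class TestLikelihood:
    def test_omega_zero_matches_closed_form(self, toy_cohort, fixed_params):
        theta, sigma = 3.6, 0.135
        val = neg2ll(theta, 0.0, sigma, toy_cohort, fixed_params)
        d = _Design(toy_cohort, fixed_params)
        c = d.rate / d.typical_cl(theta)
        m2ll = 0.0
        for i in range(d.n_pat):
            for y in d.y[i, d.mask[i]]:
                f = c[i]
                m2ll += (math.log(2 * math.pi) + 2 * math.log(sigma * f)
                         + ((y - f) / (sigma * f)) ** 2)
        assert val == pytest.approx(m2ll, rel=1e-12)

    @pytest.mark.parametrize("params", [
        (3.6, 0.149, 0.135), (2.0, 0.3, 0.2), (5.0, 0.05, 0.1)])
    def test_laplace_agrees_with_bruteforce_integration(self, params,
                                                        toy_cohort, fixed_params):
        """Laplace -2LL within 0.05 of a 201-node trapezoid over [-6w, 6w]."""
        lap = neg2ll(*params, toy_cohort, fixed_params, method="laplace")
        brute = neg2ll_bruteforce(*params, toy_cohort, fixed_params)
        assert lap == pytest.approx(brute, abs=0.05)

    def test_quadrature_converged_in_nodes(self, toy_cohort, fixed_params):
        q21 = neg2ll(3.6, 0.149, 0.135, toy_cohort, fixed_params,
                     method="quadrature", n_nodes=21)
        q41 = neg2ll(3.6, 0.149, 0.135, toy_cohort, fixed_params,
                     method="quadrature", n_nodes=41)
        assert abs(q21 - q41) < 1e-4

    def test_quadrature_agrees_with_bruteforce(self, toy_cohort, fixed_params):
        q = neg2ll(2.0, 0.3, 0.2, toy_cohort, fixed_params,
                   method="quadrature", n_nodes=41)
        brute = neg2ll_bruteforce(2.0, 0.3, 0.2, toy_cohort, fixed_params,
                                  n_grid=2001)
        assert q == pytest.approx(brute, abs=1e-6)

    def test_invariant_to_patient_order(self, fixed_params):
        data = gen_cohort(CohortSpec(n_patients=8, seed=13), fixed_params)
        shuffled = PopPKDataset(
            data.frame.sample(frac=1.0, random_state=4).reset_index(drop=True))
        a = neg2ll(3.6, 0.149, 0.135, data, fixed_params)
        b = neg2ll(3.6, 0.149, 0.135, shuffled, fixed_params)
        assert a == pytest.approx(b, rel=1e-12)

    def test_dataset_duplication_doubles_minus2ll(self, fixed_params):
        data = gen_cohort(CohortSpec(n_patients=5, seed=17), fixed_params)
        dup = data.frame.copy()
        dup["id"] = dup["id"] + 1000
        doubled = PopPKDataset(pd.concat([data.frame, dup], ignore_index=True))
        a = neg2ll(3.6, 0.149, 0.135, data, fixed_params)
        b = neg2ll(3.6, 0.149, 0.135, doubled, fixed_params)
        assert b == pytest.approx(2.0 * a, rel=1e-12)

    def test_rejects_invalid_variances(self, toy_cohort, fixed_params):
        with pytest.raises(ValueError):
            neg2ll(3.6, -0.1, 0.1, toy_cohort, fixed_params)
        with pytest.raises(ValueError):
            neg2ll(3.6, 0.1, 0.0, toy_cohort, fixed_params)


class TestEstimation:
    def test_noise_free_theta_recovery(self, fixed_params):
        """With variance components pinned, noise-free data return theta exactly."""
        data = gen_cohort(CohortSpec(n_patients=6, seed=5), fixed_params,
                          omega_cl=0.0, sigma_prop=0.0)
        res = fit_poppk(data, fixed_params, n_starts=2, seed=0,
                        fix={"omega": 0.0, "sigma": 1e-5})
        assert res.theta_cl_nongfr == pytest.approx(3.6, abs=1e-6)

    def test_deterministic_fit(self, fixed_params):
        data = gen_cohort(CohortSpec(n_patients=20, seed=29), fixed_params)
        r1 = fit_poppk(data, fixed_params, seed=6)
        r2 = fit_poppk(data, fixed_params, seed=6)
        assert r1.theta_cl_nongfr == r2.theta_cl_nongfr
        assert r1.omega_cl == r2.omega_cl
        assert r1.minus2ll == r2.minus2ll

    def test_recovers_population_parameters_at_n300(self, fit300):
        assert fit300.theta_cl_nongfr == pytest.approx(3.6, rel=0.10)
        assert fit300.omega_cv_percent == pytest.approx(14.9, rel=0.15)
        assert fit300.sigma_cv_percent == pytest.approx(13.5, rel=0.15)
        assert fit300.status == "converged"

    def test_reports_uncertainty_and_shrinkage(self, fit300):
        assert 0 < fit300.rse["theta_cl_nongfr"] < 50
        assert 0 < fit300.rse["omega_cl"] < 50
        assert 0 < fit300.rse["sigma_prop"] < 50
        assert fit300.eta_shrinkage < 100
        assert fit300.eps_shrinkage < 100
        assert fit300.ofv_nonmem == pytest.approx(
            fit300.minus2ll - 1200 * math.log(2 * math.pi))

    def test_parameter_recovery_bias_and_coverage(self, fixed_params):
        """50 replicates of n=100: |mean bias| < 3%, Wald coverage in 90-99%."""
        thetas, covered = [], 0
        z = 1.959963984540054
        for rep in range(50):
            data = gen_cohort(CohortSpec(n_patients=100, seed=1000 + rep),
                              fixed_params)
            res = fit_poppk(data, fixed_params, n_starts=2, seed=rep)
            thetas.append(res.theta_cl_nongfr)
            se = res.rse["theta_cl_nongfr"] / 100.0 * res.theta_cl_nongfr
            if np.isfinite(se) and abs(res.theta_cl_nongfr - 3.6) <= z * se:
                covered += 1
        mean_bias = abs(np.mean(thetas) - 3.6) / 3.6
        assert mean_bias < 0.03
        assert 0.90 * 50 <= covered <= 0.99 * 50 + 1e-9

    def test_too_few_patients_rejected(self, fixed_params):
        data = gen_cohort(CohortSpec(n_patients=1, seed=0), fixed_params)
        with pytest.raises(EstimationError):
            fit_poppk(data, fixed_params)


class TestPartition:
    def test_reported_components_total(self):
        p = ClearancePartition.from_components(7.1, 3.6, 0.66)
        assert round(p.cl_total, 1) == 11.4
        assert p.integer_fractions() == (62, 32, 6)

    def test_fractions_sum_exactly(self):
        for comps in [(7.1, 3.6, 0.66), (1.0, 1.0, 1.0), (5.0, 0.1, 0.01)]:
            p = ClearancePartition.from_components(*comps)
            assert sum(p.fractions) == pytest.approx(100.0, abs=1e-9)
            assert sum(p.integer_fractions()) == 100

    def test_single_component(self):
        p = ClearancePartition.from_components(5.0, 0.0, 0.0)
        assert p.integer_fractions() == (100, 0, 0)

    def test_partition_from_fit(self, fit300, cohort300):
        fx = FixedParams()
        mean_gfr = float(cohort300.patient_table()["gfr_ml_min"].mean())
        p = partition_clearance(fit300, fx, mean_gfr)
        assert p.cl_gfr == pytest.approx(0.06 * mean_gfr)
        assert p.cl_total == pytest.approx(
            p.cl_gfr + p.cl_nongfr + p.cl_decay, rel=1e-12)


class TestDiagnostics:
    def test_noise_free_population_prediction_equals_observation(self, fixed_params):
        data = gen_cohort(CohortSpec(n_patients=4, seed=2), fixed_params,
                          omega_cl=0.0, sigma_prop=0.0)
        res = fit_poppk(data, fixed_params, n_starts=2, seed=0,
                        fix={"omega": 0.0, "sigma": 1e-5})
        gof = gof_tables(res, data, fixed_params)
        assert np.allclose(gof["dv_mg_L"], gof["pred_mg_L"], rtol=1e-5)

    def test_identity_slope_on_simulated_data(self, fit300, cohort300):
        """Observed vs individual-predicted regression slope near 1."""
        gof = gof_tables(fit300, cohort300, FixedParams())
        slope = np.polyfit(gof["ipred_mg_L"], gof["dv_mg_L"], 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_ebe_shrinks_to_zero_at_typical_prediction(self, fixed_params):
        """A patient observed exactly at the typical Css has EBE ~ 0."""
        theta, gfr, rate = 3.6, 139.0, 250.0
        tv = fixed_params.gfr_to_clearance_factor * gfr + theta + fixed_params.cl_decay
        css = rate / tv
        frame = pd.DataFrame({
            "id": [1, 1, 1], "time_h": [48.0, 72.0, 96.0],
            "dv_mg_L": [css] * 3, "analyte": ["meropenem"] * 3,
            "rate_mg_h": [rate] * 3, "gfr_ml_min": [gfr] * 3})
        ebe = empirical_bayes(theta, 0.149, 0.135, PopPKDataset(frame),
                              fixed_params)
        # the proportional-error Jacobian term leaves an O(n*sigma^2) offset,
        # far inside the prior spread omega = 0.149
        assert abs(ebe["eta"].iloc[0]) < 0.02
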