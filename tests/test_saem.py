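"""SAEM estimation engine: determinism, limits, oracles and metrics."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

from txapk import saem, trial
from txapk.data import DoseEvent, Observation, PKDataset
from txapk.saem import (FitData, PopulationModel, SaemSettings, compute_bicc,
                        log_likelihood, saem_fit, shapiro_wilk_check, wald_test)
from txapk.structural import StructuralSpec

from conftest import quick_settings

SPEC_1C = StructuralSpec(1, "first_order", "none", "none")


def toy_dataset(n_sub=24, times=(15.0, 60.0, 120.0, 240.0), omega_cl=0.25,
                omega_v1=0.25, sd_add=0.4, seed=11, theta_cl=0.10, theta_v1=10.0):
    """One-compartment plasma-only trial with additive error (no urine)."""
    rng = np.random.default_rng(seed)
    subjects = trial.sample_covariates(n_sub, rng, arm="TXA1g")
    doses = [DoseEvent(subject=s.id, time=0.0, amount=1000.0) for s in subjects]
    obs = []
    for i, s in enumerate(subjects):
        cl = theta_cl * math.exp(omega_cl * rng.standard_normal())
        v1 = theta_v1 * math.exp(omega_v1 * rng.standard_normal())
        for t in times:
            f = 1000.0 / v1 * math.exp(-cl / v1 * t)
            obs.append(Observation(subject=s.id, time=t,
                                   value=max(f + sd_add * rng.standard_normal(), 0.0)))
    return PKDataset(subjects=subjects, doses=doses, observations=obs)


def toy_model():
    return PopulationModel(
        spec=SPEC_1C, theta={"CL": 0.0, "V1": 0.0}, omega={},
        error_plasma={"model": "additive", "a": 0.5},
        error_urine={"model": "proportional", "b": 0.3})


class TestSaemCore:
    def test_seeded_determinism(self, small_trial):
        ds, _ = small_trial
        model = PopulationModel(spec=trial.DUAL_2CMT,
                                theta={n: 0.0 for n in trial.DUAL_2CMT.param_names()},
                                omega={})
        s = quick_settings(seed=3, n_explore=60, n_smooth=30)
        f1 = saem_fit(ds, model, s)
        f2 = saem_fit(ds, model, s)
        assert f1.model.theta == f2.model.theta
        assert f1.model.omega == f2.model.omega
        assert np.array_equal(f1.etas, f2.etas)

    def test_no_bsv_limit_recovers_pooled_regression(self):
        # data simulated with omega = 0 and tiny residual error: the fit
        # degenerates to pooled nonlinear regression and recovers theta ~1%
        ds = toy_dataset(n_sub=20, omega_cl=0.0, omega_v1=0.0, sd_add=0.01)
        fit = saem_fit(ds, toy_model(), quick_settings(seed=4, n_explore=200,
                                                       n_smooth=100))
        assert fit.model.theta["CL"] == pytest.approx(0.10, rel=0.01)
        assert fit.model.theta["V1"] == pytest.approx(10.0, rel=0.01)
        assert fit.model.omega["CL"] < 0.05

    def test_matches_quadrature_mle_oracle(self):
        """SAEM agrees with a direct marginal-likelihood MLE computed by
        adaptive Gauss-Hermite quadrature (mode-centred, Laplace-scaled)."""
        ds = toy_dataset(n_sub=20, seed=17)
        fit = saem_fit(ds, toy_model(), quick_settings(seed=5, n_explore=300,
                                                       n_smooth=200))

        fd = FitData(ds)
        dose = 1000.0
        t_by, y_by = [], []
        for sid in fd.ids:
            pts = [(o.time, o.value) for o in ds.observations if o.subject == sid]
            t_by.append(np.array([p[0] for p in pts]))
            y_by.append(np.array([p[1] for p in pts]))
        nodes, wts = np.polynomial.hermite_e.hermegauss(15)
        Z = np.array(np.meshgrid(nodes, nodes)).reshape(2, -1).T      # (225, 2)
        logW = np.log(np.outer(wts, wts)).ravel() + 0.5 * (Z ** 2).sum(axis=1)
        mode_cache = {}

        def neg_marginal_ll(x):
            lcl, lv1, lo1, lo2, la = x
            o1, o2, a = math.exp(lo1), math.exp(lo2), math.exp(la)
            total = 0.0
            for i, (t, y) in enumerate(zip(t_by, y_by)):
                def njoint(e, grad=False):
                    cl = math.exp(lcl + e[0])
                    v1 = math.exp(lv1 + e[1])
                    k = cl / v1
                    f = dose / v1 * np.exp(-k * t)
                    r = (f - y) / a ** 2
                    val = (0.5 * np.sum(((y - f) / a) ** 2)
                           + len(t) * math.log(a)
                           + 0.5 * (e[0] ** 2 / o1 ** 2 + e[1] ** 2 / o2 ** 2))
                    if not grad:
                        return val
                    g0 = np.sum(r * f * (-t * k)) + e[0] / o1 ** 2
                    g1 = np.sum(r * f * (t * k - 1.0)) + e[1] / o2 ** 2
                    return val, np.array([g0, g1])

                res = optimize.minimize(
                    lambda e: njoint(e, grad=True), mode_cache.get(i, np.zeros(2)),
                    jac=True, method="BFGS", options={"gtol": 1e-8})
                mode_cache[i] = res.x
                h = 1e-4
                H = np.empty((2, 2))
                for r_ in range(2):
                    ei = np.eye(2)[r_] * h
                    H[r_] = (njoint(res.x + ei, grad=True)[1]
                             - njoint(res.x - ei, grad=True)[1]) / (2 * h)
                H = 0.5 * (H + H.T)
                C = np.linalg.cholesky(np.linalg.inv(H))
                etas = res.x + Z @ C.T
                cl = np.exp(lcl + etas[:, 0])
                v1 = np.exp(lv1 + etas[:, 1])
                f = dose / v1[:, None] * np.exp(-(cl / v1)[:, None] * t)
                logjoint = (-0.5 * np.sum(((y - f) / a) ** 2, axis=1)
                            - len(t) * math.log(a)
                            - 0.5 * (etas[:, 0] ** 2 / o1 ** 2 + etas[:, 1] ** 2 / o2 ** 2))
                const = (-0.5 * len(t) * math.log(2 * math.pi)
                         - math.log(2 * math.pi * o1 * o2))
                _, logdet = np.linalg.slogdet(C)
                m = np.max(logjoint + logW)
                total += (math.log(np.sum(np.exp(logjoint + logW - m))) + m
                          + logdet + const)
            return -total

        x0 = np.log([0.1, 10.0, 0.25, 0.25, 0.4])
        res = optimize.minimize(neg_marginal_ll, x0, method="Nelder-Mead",
                                options={"maxiter": 1500, "xatol": 1e-5,
                                         "fatol": 1e-7})
        mle = np.exp(res.x)
        assert fit.model.theta["CL"] == pytest.approx(mle[0], rel=0.03)
        assert fit.model.theta["V1"] == pytest.approx(mle[1], rel=0.03)
        assert fit.model.omega["CL"] == pytest.approx(mle[2], abs=0.05)
        assert fit.model.omega["V1"] == pytest.approx(mle[3], abs=0.05)
        assert fit.model.error_plasma["a"] == pytest.approx(mle[4], rel=0.2)

    def test_too_few_subjects(self):
        ds = toy_dataset(n_sub=1)
        with pytest.raises(ValueError):
            saem_fit(ds, toy_model(), quick_settings())


class TestLikelihoodAndBicc:
    def test_no_bsv_importance_sampling_exact(self, small_trial):
        # with omega ~ 0 the marginal integral collapses: IS equals the
        # direct residual log-likelihood
        ds, _ = small_trial
        fd = FitData(ds)
        model = trial.final_model()
        model.omega = {k: 1e-10 for k in model.omega}
        stub = type("Stub", (), {})()
        stub.etas = np.zeros((fd.n_sub, 5))
        stub.eta_sd = np.full((fd.n_sub, 5), 1e-10)
        m2ll, _ = log_likelihood(fd, model, stub, mc_size=200, seed=1)
        from txapk.saem import _natural_psi, _subject_loglik
        direct = -2.0 * _subject_loglik(
            model, fd, _natural_psi(model, fd, np.zeros((fd.n_sub, 5)))).sum()
        assert m2ll == pytest.approx(direct, abs=1e-6 * abs(direct) + 1e-6)

    def test_mc_se_scales_with_draws(self, fit79):
        fd = fit79.fitdata
        _, se1 = log_likelihood(fd, fit79.model, fit79, mc_size=400, seed=2)
        _, se2 = log_likelihood(fd, fit79.model, fit79, mc_size=1600, seed=2)
        assert se2 < se1  # quadrupling draws should halve the SE
        assert se1 / se2 == pytest.approx(2.0, rel=0.6)

    def test_bicc_hand_computed_penalty(self, fit79):
        model = fit79.model
        fd = fit79.fitdata
        # 5 fixed effects + 2 covariate betas + 5 omegas -> log(N);
        # a1, b1, b2 -> log(n_obs)
        penalty = 12 * math.log(fd.n_sub) + 3 * math.log(fd.n_obs)
        assert compute_bicc(100.0, model, fd) == pytest.approx(100.0 + penalty)

    def test_bicc_penalises_extra_parameter(self, fit79):
        model = fit79.model
        fd = fit79.fitdata
        richer = trial.final_model()  # same structure, same dims
        from txapk.structural import CovariateRelation
        richer.betas = richer.betas + [(CovariateRelation("Q", "AGE", "linear"), 0.0)]
        assert compute_bicc(50.0, richer, fd) > compute_bicc(50.0, model, fd)

    def test_nested_model_dominance(self, small_trial):
        # a richer model cannot fit worse than its restriction (up to MC noise)
        ds, _ = small_trial
        single = StructuralSpec(2, "first_order", "none", "none")
        s = quick_settings(seed=6, compute_ll=True, ll_draws=1500)
        f_single = saem_fit(ds, PopulationModel(
            spec=single, theta={n: 0.0 for n in single.param_names()}, omega={}), s)
        f_dual = saem_fit(ds, PopulationModel(
            spec=trial.DUAL_2CMT,
            theta={n: 0.0 for n in trial.DUAL_2CMT.param_names()}, omega={}), s)
        noise = 3.0 * (f_single.ll_se + f_dual.ll_se)
        assert f_dual.minus2LL <= f_single.minus2LL + noise


class TestInformationMetrics:
    def test_rse_standards_on_replicate(self, fit79):
        # precision standards: <=30% for fixed effects, <=50% for omegas
        for key, v in fit79.rse.items():
            if key.startswith("theta_") or key.startswith("beta_"):
                assert v <= 30.0, f"{key}: RSE {v:.1f}%"
            if key.startswith("omega_"):
                assert v <= 50.0, f"{key}: RSE {v:.1f}%"
        assert 1.0 <= fit79.kappa < 100.0

    def test_shrinkage_vanishes_with_rich_sampling(self):
        # dense sampling per subject pins the individual parameters down:
        # the empirical-Bayes means approach the true etas and shrinkage -> 0
        ds = toy_dataset(n_sub=12, times=tuple(np.linspace(10.0, 350.0, 24)),
                         seed=21)
        fit = saem_fit(ds, toy_model(), quick_settings(seed=8, n_explore=150,
                                                       n_smooth=80))
        assert abs(fit.shrinkage["CL"]) < 20.0
        assert abs(fit.shrinkage["V1"]) < 20.0

    def test_shrinkage_moderate_on_sparse_trial(self, fit79):
        for name in ("CL", "V1", "p_urine"):
            assert -20.0 < fit79.shrinkage[name] < 60.0

    def test_shrinkage_uninformative_data_near_total(self):
        # subjects dosed but never observed: conditional means collapse to 0
        rng = np.random.default_rng(0)
        subjects = trial.sample_covariates(6, rng, arm="TXA1g")
        ds = PKDataset(
            subjects=subjects,
            doses=[DoseEvent(subject=s.id, time=0.0, amount=1000.0) for s in subjects],
            observations=[])
        fit = saem_fit(ds, toy_model(), quick_settings(seed=7, n_explore=60,
                                                       n_smooth=30))
        assert fit.shrinkage["CL"] > 80.0
        assert fit.shrinkage["V1"] > 80.0


class TestWaldAndShapiro:
    def test_wald_examples(self):
        assert wald_test(0.0, 1.0) == pytest.approx(1.0)
        assert wald_test(1.96, 1.0) == pytest.approx(0.05, abs=1e-3)
        assert wald_test(3.89, 1.0) == pytest.approx(1.0e-4, rel=0.05)
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)

    def test_shapiro_type_one_error(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(79)
            _, p = shapiro_wilk_check(x)
            hits += p > 0.05
        assert hits >= 90

    def test_shapiro_power_against_exponential(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=79)
            _, p = shapiro_wilk_check(x)
            hits += p < 0.05
        assert hits >= 90

    def test_shapiro_preconditions(self):
        with pytest.raises(ValueError):
            shapiro_wilk_check([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk_check([1.0, 1.0, 1.0])


class TestErrorModels:
    def test_exponential_equivalent_to_log_additive(self, rng):
        # the exponential model's density equals the additive-on-log-scale
        # density with the change-of-variables Jacobian, so fits coincide
        from txapk.saem import _obs_loglik
        f = rng.uniform(1.0, 50.0, 200)
        y = f * np.exp(0.2 * rng.standard_normal(200))
        ll_exp = _obs_loglik(y, f, {"model": "exponential", "a": 0.2})
        ll_log = (stats.norm.logpdf(np.log(y), np.log(f), 0.2) - np.log(y))
        assert np.allclose(ll_exp, ll_log, atol=1e-10)

    def test_combined_error_sd(self):
        from txapk.saem import _error_sd
        f = np.array([0.0, 10.0])
        g = _error_sd({"model": "combined", "a": 0.44, "b": 0.15}, f)
        assert g[0] == pytest.approx(0.44)
        assert g[1] == pytest.approx(math.hypot(0.44, 1.5))
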