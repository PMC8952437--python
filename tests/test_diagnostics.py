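"""VPC, NPDE and bootstrap diagnostics."""

import numpy as np
import pytest

from txapk import diagnostics, saem, trial
from txapk.data import DoseEvent, Observation, PKDataset
from txapk.saem import FitData, simulate_observations
from txapk.structural import StructuralParams, predict_profile


class TestVPC:
    def test_self_consistency_under_true_model(self, trial79):
        ds, ledger = trial79
        v = diagnostics.vpc(ds, ledger["model"], n_sim=300, seed=1)
        assert v.coverage() >= 0.8

    def test_detects_misspecified_volume(self, trial79):
        ds, _ = trial79
        bad = trial.final_model()
        bad.theta["V1"] *= 2.0
        v = diagnostics.vpc(ds, bad, n_sim=300, seed=1)
        j = 0  # earliest bin, where V1 dominates
        assert not (v.band_lo[1, j] <= v.observed[1, j] <= v.band_hi[1, j])

    def test_zero_variability_bands_collapse(self, trial79):
        ds, _ = trial79
        degenerate = trial.final_model()
        degenerate.omega = {k: 0.0 for k in degenerate.omega}
        degenerate.error_plasma = {"model": "additive", "a": 1e-12}
        degenerate.error_urine = {"model": "proportional", "b": 1e-12}
        v = diagnostics.vpc(ds, degenerate, n_sim=120, seed=2)
        # within a time bin only covariate differences remain; band width
        # collapses far below the observed spread
        width = v.band_hi[1] - v.band_lo[1]
        obs_spread = v.observed[2] - v.observed[0]
        assert np.all(width < 0.6 * obs_spread)

    def test_warns_below_100_simulations(self, small_trial):
        ds, ledger = small_trial
        with pytest.warns(UserWarning, match="100"):
            diagnostics.vpc(ds, ledger["model"], n_sim=20, seed=3)

    def test_matches_bruteforce_simulator(self, small_trial):
        """The VPC consumes only the model's simulation interface: an
        independently coded per-subject brute-force simulator produces the
        same percentile summaries within Monte Carlo tolerance."""
        ds, ledger = small_trial
        model = ledger["model"]
        fd = FitData(ds)
        n_sim = 300
        v = diagnostics.vpc(fd, model, n_sim=n_sim, seed=11)

        rng = np.random.default_rng(1234)
        names = model.param_names()
        plasma = [o for o in ds.observations if o.kind == "plasma"]
        panel = fd.panel
        meds = []
        for _ in range(n_sim):
            sim_vals = {}
            for sid in fd.ids:
                mu = {}
                for n in names:
                    m = model.to_transformed(n, model.theta[n])
                    for rel, b in model.betas_for(n):
                        m += b * float(np.asarray(
                            rel.design_value(panel.loc[sid, rel.covariate])))
                    mu[n] = m + model.omega[n] * rng.standard_normal()
                params = StructuralParams(
                    CL=np.exp(mu["CL"]), V1=np.exp(mu["V1"]), Q=np.exp(mu["Q"]),
                    V2=np.exp(mu["V2"]),
                    p_urine=float(1 / (1 + np.exp(-mu["p_urine"]))))
                doses = [d for d in ds.doses if d.subject == sid]
                times = sorted(o.time for o in plasma if o.subject == sid)
                prof = predict_profile(model.spec, params, doses, np.array(times))
                g = np.sqrt(model.error_plasma["a"] ** 2
                            + (model.error_plasma["b"] * prof.plasma) ** 2)
                vals = np.maximum(prof.plasma + g * rng.standard_normal(len(times)), 0)
                for t, val in zip(times, vals):
                    sim_vals.setdefault(round(t / 60), []).append(val)
            meds.append(np.median(np.concatenate(
                [np.asarray(v_) for v_ in sim_vals.values()])))
        # compare the overall median level of the two simulators
        own = np.median(v.band_med[1])
        assert np.median(meds) == pytest.approx(own, rel=0.25)


class TestNPDE:
    def test_calibrated_under_true_model(self, trial79):
        ds, ledger = trial79
        r = diagnostics.npde(ds, ledger["model"], n_sim=400, seed=4)
        assert abs(r.npde.mean()) <= 0.1
        assert 0.8 <= r.npde.var() <= 1.2
        assert 0.02 <= r.outside90_plasma <= 0.2
        # reporting is split by observation type, as for plasma vs urine
        assert r.shapiro_plasma[1] >= 0.0 and r.shapiro_urine[1] >= 0.0

    def test_single_observation_reduces_to_marginal_rank(self):
        rng = np.random.default_rng(0)
        subjects = trial.sample_covariates(5, rng, arm="TXA1g")
        doses = [DoseEvent(subject=s.id, time=0.0, amount=1000.0) for s in subjects]
        obs = [Observation(subject=s.id, time=30.0, value=20.0 + i)
               for i, s in enumerate(subjects)]
        ds = PKDataset(subjects=subjects, doses=doses, observations=obs)
        model = trial.final_model()
        K = 200
        r = diagnostics.npde(ds, model, n_sim=K, seed=7)
        # manual marginal rank transform with an identical simulation stream
        fd = FitData(ds)
        rng2 = np.random.default_rng(7)
        sims = np.stack([simulate_observations(model, fd, rng2)[0]
                         for _ in range(K)])
        from scipy import stats
        manual = stats.norm.ppf(
            ((sims < fd.y_plasma).sum(axis=0) + 0.5) / (K + 1.0))
        assert np.allclose(r.npde_plasma, manual)


class TestBootstrap:
    def test_smoke_run_preserves_invariants(self, small_trial):
        ds, ledger = small_trial
        b = diagnostics.bootstrap(ds, ledger["model"], n_rep=2, seed=5)
        assert b.n_requested == 2
        assert b.n_converged + b.n_failed == 2
        for name, (med, q1, q3) in b.table.items():
            assert q1 <= med <= q3

    def test_cloned_subjects_shrink_iqr(self):
        # a trial of identical cloned subjects leaves nothing to resample:
        # the interquartile range collapses to refit Monte Carlo noise
        from dataclasses import replace
        design = trial.TrialDesign(
            n_per_arm={"TXA1g": 8}, rescue_probability=0.0,
            nominal_times=(10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0,
                           180.0, 240.0, 300.0, 360.0))
        truth = trial.GenerativeTruth()
        truth.model.omega = {k: 1e-8 for k in truth.model.omega}
        ds, _ = trial.generate_trial(design=design, truth=truth, seed=6)
        first = ds.subjects[0]
        tpl_obs = [o for o in ds.observations if o.subject == first.id]
        subjects = [replace(first, id=f"C{k:02d}") for k in range(8)]
        clones = PKDataset(
            subjects=subjects,
            doses=[DoseEvent(subject=s.id, time=0.0, amount=1000.0)
                   for s in subjects],
            observations=[replace(o, subject=s.id)
                          for s in subjects for o in tpl_obs])
        # covariate-free structure: with a single shared covariate value an
        # uncentred covariate intercept would be unidentifiable
        model = trial.base_model()
        settings = saem.SaemSettings(n_explore=200, n_smooth=250, n_chains=2,
                                     compute_fim=False, compute_ll=False)
        b = diagnostics.bootstrap(clones, model, n_rep=4, seed=8,
                                  settings=settings)
        med, q1, q3 = b.table["theta_CL"]
        assert (q3 - q1) <= 0.05 * med
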