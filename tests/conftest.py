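import numpy as np
import pytest

from txapk import saem, trial


@pytest.fixture(scope="session")
def trial79():
    """Full-size synthetic trial (34 + 45 subjects) with its truth ledger."""
    return trial.generate_trial(seed=0)


@pytest.fixture(scope="session")
def fit79(trial79):
    """SAEM refit of the full-size trial with FIM and likelihood."""
    dataset, _ = trial79
    model = saem.PopulationModel(
        spec=trial.DUAL_2CMT,
        theta={"CL": 0.0, "V1": 0.0, "Q": 0.0, "V2": 0.0, "p_urine": 0.0},
        betas=[(trial.FINAL_RELATIONS[0], 0.0), (trial.FINAL_RELATIONS[1], 0.0)],
        omega={})
    settings = saem.SaemSettings(n_explore=300, n_smooth=150, n_chains=5,
                                 seed=42, ll_draws=1000)
    return saem.saem_fit(dataset, model, settings)


@pytest.fixture(scope="session")
def small_trial():
    """A reduced 14-subject trial for fast refits."""
    design = trial.TrialDesign(n_per_arm={"TXA0.5g": 6, "TXA1g": 8})
    return trial.generate_trial(design=design, seed=5)


def quick_settings(seed=0, **kw):
    defaults = dict(n_explore=150, n_smooth=75, n_chains=2, ll_draws=800,
                    seed=seed, compute_fim=False, compute_ll=False)
    defaults.update(kw)
    return saem.SaemSettings(**defaults)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
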