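"""Shared fixtures: small synthetic datasets and first-stage draw stores.

Session-scoped because first-stage sampling is the expensive step; tests must
not mutate the fixtures (take copies instead).
"""

import numpy as np
import pytest
from hypothesis import settings

from hierpk.stage1_mcmc import Stage1Config, run_stage1_dataset

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from hierpk.synthetic_trial import TrialDesign, generate_trial


@pytest.fixture(scope="session")
def onelevel_dataset():
    """8 profiles (2 women x 2 visits x 2 meals) from a one-level truth,
    no covariate effects."""
    design = TrialDesign(n_women=2, n_study1_women=1, level="one", beta_true=())
    dataset, truth = generate_trial(design, seed=7)
    return dataset, truth


@pytest.fixture(scope="session")
def onelevel_store(onelevel_dataset):
    """First-stage store for the 8-profile dataset, sized so the stored draw
    pool supports long second-stage runs."""
    dataset, _ = onelevel_dataset
    config = Stage1Config(burn_in=5000, iterations=20000, thin=10)
    return run_stage1_dataset(dataset, config=config, seed=21)


@pytest.fixture(scope="session")
def twolevel_dataset():
    """12 profiles (3 women) from a two-level truth, no covariate effects."""
    design = TrialDesign(n_women=3, n_study1_women=1, level="two", beta_true=())
    dataset, truth = generate_trial(design, seed=9)
    return dataset, truth


@pytest.fixture(scope="session")
def twolevel_store(twolevel_dataset):
    dataset, _ = twolevel_dataset
    config = Stage1Config(burn_in=4000, iterations=12000, thin=12)
    return run_stage1_dataset(dataset, config=config, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
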