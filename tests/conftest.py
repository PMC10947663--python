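"""Shared fixtures: reference parameter sets and small simulated screens."""

from __future__ import annotations

import numpy as np
import pytest

import bdmix as bm


@pytest.fixture(scope="session")
def fig2_model() -> bm.MixtureModel:
    """Two-subpopulation near-critical mixture used for the Gaussian
    approximation studies (no drug effect is exercised with it)."""
    hp = bm.HillParams(b=0.85, E=1.0, m=3.0)  # inert at dose 0
    return bm.MixtureModel(
        subpops=[
            bm.Subpopulation(p=0.4629, beta=0.9058, nu=0.8101, hill=hp),
            bm.Subpopulation(p=0.5371, beta=0.2785, nu=0.2300, hill=hp),
        ],
        n=1000, c=0.0)


@pytest.fixture(scope="session")
def case_study_model() -> bm.MixtureModel:
    """Sensitive/resistant case-study parameter set (moderate noise)."""
    return bm.MixtureModel(
        subpops=[
            bm.Subpopulation(p=0.4856, beta=0.1163, nu=0.0176,
                             hill=bm.HillParams(b=0.8262, E=0.0674, m=4.5404)),
            bm.Subpopulation(p=0.5144, beta=0.4624, nu=0.3978,
                             hill=bm.HillParams(b=0.8062, E=1.5776, m=4.2002)),
        ],
        n=1000, c=1.2103)


@pytest.fixture(scope="session")
def standard_design() -> bm.ExperimentDesign:
    """Canonical live-cell screen layout: long grid, 11 doses, 14 replicates."""
    return bm.ExperimentDesign(times=bm.LONG_TIME_GRID,
                               doses=bm.default_dose_grid(),
                               n_replicates=14, mode="livecell")


@pytest.fixture(scope="session")
def small_livecell_data(case_study_model, standard_design) -> bm.Dataset:
    rng = np.random.default_rng(20240301)
    return bm.simulate_dataset(case_study_model, standard_design, rng)


@pytest.fixture(scope="session")
def tiny_design() -> bm.ExperimentDesign:
    """Cut-down grid for fast fitting tests."""
    return bm.ExperimentDesign(times=(0.0, 6.0, 12.0, 18.0, 24.0, 30.0, 36.0),
                               doses=np.geomspace(0.01, 10.0, 7),
                               n_replicates=6, mode="livecell")
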