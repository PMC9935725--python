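"""Shared fixtures: small simulated datasets and a reusable tiny fit."""

import numpy as np
import pytest

from contextddm.datasets import ExperimentDesign
from contextddm.inference import fit
from contextddm.models import (IndividualParameters, ModelSpec,
                               sample_individual_parameters)
from contextddm.wiener import simulate_experiment

#: group-level posterior modes of the auditory experiment (starting-point
#: regression variant with separate stimulus weights); used as generating
#: values throughout the synthetic tests
TABLE2_EXP1_MODES = {"a": 1.4736, "tau": 0.1456, "z0": 0.4411,
                     "v0": 0.0437, "v1": 0.0096, "v2": -0.0198,
                     "z1": 0.0007}

#: modest between-participant spread on the unconstrained scales
DEFAULT_GROUP_SDS = {"a": 0.15, "tau": 0.2, "z0": 0.15, "v0": 0.15,
                     "v1": 0.002, "v2": 0.004, "z1": 0.0003}


def make_cohort_dataset(n_participants, reps_per_cell, seed,
                        model_number=6, group_means=None, group_sds=None,
                        levels=9):
    """Simulate a duration-discrimination cohort from one model variant."""
    spec = ModelSpec.from_number(model_number)
    design = ExperimentDesign(
        comparison_levels_ms=tuple(np.linspace(400.0, 600.0, levels)),
        n_trials_per_level_per_order=reps_per_cell)
    rng = np.random.default_rng(seed)
    params = sample_individual_parameters(
        group_means or TABLE2_EXP1_MODES,
        group_sds if group_sds is not None else DEFAULT_GROUP_SDS,
        n_participants, rng=rng)
    ds = simulate_experiment(design, spec, params, rng=rng)
    return spec, design, params, ds


@pytest.fixture(scope="session")
def table2_modes():
    return dict(TABLE2_EXP1_MODES)


@pytest.fixture(scope="session")
def two_participant_dataset():
    """144-trial, two-participant dataset simulated from the separate-weight
    starting-point model."""
    spec, design, params, ds = make_cohort_dataset(2, 4, seed=101)
    return spec, design, params, ds


@pytest.fixture(scope="session")
def small_fit(two_participant_dataset):
    """A deliberately short hierarchical fit reused by LOO/PPC tests
    (posterior quality is irrelevant to the contracts tested with it)."""
    spec, design, params, ds = two_participant_dataset
    draws = fit(spec, ds, n_chains=2, n_iter=300, seed=7)
    return spec, design, ds, draws


@pytest.fixture()
def single_params():
    return IndividualParameters(a=1.4736, tau=0.1456, z0=0.4411, v0=0.0437,
                                v1=0.0096, v2=-0.0198, z1=0.0007)
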