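"""Shared synthetic study fixtures.

The expensive objects — the planted landscape, its Gibbs sample, the
pseudolikelihood refit and the strain panel — are session-scoped so the
whole suite pays for them once. Seeds are fixed; every fixture is a pure
function of them.
"""

import numpy as np
import pytest

import dcaland as d
from dcaland.synth import low_energy_reference

# Desk-scale planted-study conditions used throughout the suite
PLANT_L = 30
PLANT_Q = 8
PLANT_PAIRS = 20
PLANT_COUPLING = 1.0
PLANT_FIELD = 1.0
SAMPLE_M = 2000
PANEL_STRAINS = 1000
PANEL_MU = 15.0
PANEL_SELECTION = 2.0


@pytest.fixture(scope="session")
def planted():
    return d.make_potts(
        PLANT_L,
        q=PLANT_Q,
        n_pairs=PLANT_PAIRS,
        coupling_scale=PLANT_COUPLING,
        field_scale=PLANT_FIELD,
        seed=11,
    )


@pytest.fixture(scope="session")
def reference(planted):
    return low_energy_reference(planted.model, seed=5)


@pytest.fixture(scope="session")
def training_msa(planted):
    return d.sample_msa(planted.model, SAMPLE_M, n_sweeps=100, thin=10, seed=12)


@pytest.fixture(scope="session")
def training_weights(training_msa):
    return d.compute_weights(training_msa, theta=0.2)


@pytest.fixture(scope="session")
def ind_model(training_msa, training_weights):
    return d.fit_ind(training_msa, training_weights)


@pytest.fixture(scope="session")
def fitted_potts(training_msa, training_weights):
    return d.fit_plm(training_msa, training_weights, d.PlmConfig())


@pytest.fixture(scope="session")
def strain_panel(planted, reference):
    return d.make_strain_panel(
        planted.model,
        reference,
        PANEL_STRAINS,
        mu=PANEL_MU,
        selection_strength=PANEL_SELECTION,
        seed=6,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_model(L=8, q=6, n_pairs=10, seed=0):
    """A dense-enough random landscape for oracle-equivalence checks."""
    return d.make_potts(L, q=q, n_pairs=n_pairs, coupling_scale=0.7, field_scale=0.8, seed=seed)


def random_residue_sequence(model, rng):
    return rng.integers(0, model.alphabet.n_residues, size=model.L)
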