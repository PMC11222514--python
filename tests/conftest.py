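"""Shared fixtures.

The trained toy models are expensive (minutes of CPU), so they are built
once per session and shared between the module-level generative tests and
the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import diffmol as dm
from diffmol.experiments import (
    conditional_optimization_experiment,
    toy_recovery_experiment,
    train_toy_conditional_models,
    train_toy_generative_model,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_generative():
    """Small model overfit on the rigid water-like template (T = 100)."""
    model, schedule = train_toy_generative_model(seed=0)
    return model, schedule


@pytest.fixture(scope="session")
def recovery_results(toy_generative):
    model, schedule = toy_generative
    return toy_recovery_experiment(seed=0, model=model, schedule=schedule)


@pytest.fixture(scope="session")
def toy_conditional():
    """Matched conditional/unconditional models on the bent-angle family."""
    return train_toy_conditional_models(seed=0)


@pytest.fixture(scope="session")
def optimization_results(toy_conditional):
    cond_model, uncond_model, schedule = toy_conditional
    return conditional_optimization_experiment(
        seed=0, cond_model=cond_model, uncond_model=uncond_model,
        schedule=schedule)


@pytest.fixture
def water_molecule():
    tpl = dm.water_template()
    return dm.MoleculeRecord(elements=list(tpl.elements), coords=tpl.coords)


@pytest.fixture
def methane_molecule():
    tpl = dm.methane_template()
    return dm.MoleculeRecord(elements=list(tpl.elements), coords=tpl.coords)


def random_toy_molecule(rng: np.random.Generator) -> dm.MoleculeRecord:
    """A random plausible record over the toy alphabet (for round trips)."""
    n = int(rng.integers(1, 8))
    elements = [dm.TOY_ALPHABET[i]
                for i in rng.integers(0, len(dm.TOY_ALPHABET), n)]
    charges = rng.integers(-1, 2, n)
    coords = rng.normal(0, 2.0, (n, 3))
    return dm.MoleculeRecord(elements=elements, coords=coords, charges=charges)
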