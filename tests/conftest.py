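"""Shared fixtures: catalogs, designs, and simulated datasets.

Expensive artifacts (the standard 4x10x3 design, simulated response sets)
are session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import bwsweight as bw
from bwsweight.catalog import PUBLISHED_UTILITIES


@pytest.fixture(scope="session")
def catalog() -> bw.OutcomeCatalog:
    return bw.DEFAULT_CATALOG


@pytest.fixture(scope="session")
def published_mu(catalog) -> np.ndarray:
    return np.array(
        [PUBLISHED_UTILITIES[o][0] for o in catalog.non_reference]
    )


@pytest.fixture(scope="session")
def standard_design(catalog) -> bw.ChoiceDesign:
    """The study layout: 4 versions x 10 choice sets x 3 of 10 outcomes."""
    return bw.generate_design(
        catalog, n_versions=4, tasks_per_version=10, items_per_task=3, seed=0
    )


@pytest.fixture(scope="session")
def nonref_design(catalog) -> bw.ChoiceDesign:
    """Same layout restricted to the 9 adverse outcomes."""
    return bw.generate_design(
        catalog, 4, 10, 3, seed=0, include_reference=False
    )


@pytest.fixture(scope="session")
def het_truth(catalog, published_mu) -> bw.TruePreferences:
    """Published means with 0.25 I between-respondent heterogeneity."""
    k = len(published_mu)
    return bw.TruePreferences(catalog, published_mu, 0.25 * np.eye(k))


@pytest.fixture(scope="session")
def homog_truth(catalog, published_mu) -> bw.TruePreferences:
    """Published means with no heterogeneity (sigma = 0)."""
    k = len(published_mu)
    return bw.TruePreferences(catalog, published_mu, np.zeros((k, k)))


@pytest.fixture(scope="session")
def responses_het(standard_design, het_truth) -> bw.ChoiceResponses:
    return bw.simulate_choices(standard_design, het_truth, 396, seed=0)


@pytest.fixture(scope="session")
def responses_homog(standard_design, homog_truth) -> bw.ChoiceResponses:
    return bw.simulate_choices(standard_design, homog_truth, 396, seed=0)


@pytest.fixture(scope="session")
def pilon_trial() -> bw.TrialDataset:
    return bw.simulate_trial(
        bw.PILON_TRIAL_ARMS, bw.pilon_trial_probs(), seed=0
    )


@pytest.fixture(scope="session")
def pilon_weights() -> bw.ComponentWeights:
    return bw.compute_weights(
        {o: v[0] for o, v in PUBLISHED_UTILITIES.items()},
        [
            "Deep surgical site infection",
            "Bone healing complication",
            "Superficial surgical site infection",
        ],
    )


@pytest.fixture(scope="session")
def hb_fit_het(responses_het):
    """One medium-length hierarchical fit reused across tests."""
    return bw.fit_hb_mnl(responses_het, n_iter=2000, burn_in=1000, seed=0)
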