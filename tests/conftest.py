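"""Shared fixtures.

The solved default-model policy is expensive enough (a few seconds) to be
worth sharing across the policy-behaviour and acceptance tests; it is
solved once per session at the desk-scale settings.
"""

import numpy as np
import pytest
from hypothesis import settings

import reachpomdp as rp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

DESK_SOLVE = dict(belief_points=500, max_alphas=60, iterations=60)


@pytest.fixture(scope="session")
def model():
    return rp.RehabModel()


@pytest.fixture(scope="session")
def policy(model):
    beliefs = rp.sample_beliefs(model, DESK_SOLVE["belief_points"], seed=1)
    return rp.perseus_solve(
        model,
        beliefs,
        max_alphas=DESK_SOLVE["max_alphas"],
        iterations=DESK_SOLVE["iterations"],
        seed=1,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
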