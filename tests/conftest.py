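"""Shared fixtures: one small grown tree and its flow solution per session.

Tree growth is the expensive step; unit tests share a 20-terminal tree
grown once.  All randomness is seeded so the suite is deterministic.
"""

import numpy as np
import pytest

from coroperf.cco import CCOParams, grow_tree
from coroperf.domain import build_annulus_domain
from coroperf.hemodynamics import solve_flow


@pytest.fixture(scope="session")
def domain():
    return build_annulus_domain()


@pytest.fixture(scope="session")
def small_params():
    return CCOParams(n_term=20, seed=1)


@pytest.fixture(scope="session")
def small_tree(domain, small_params):
    return grow_tree(domain, "RCA", small_params)


@pytest.fixture(scope="session")
def small_flow(small_tree):
    return solve_flow(small_tree)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
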