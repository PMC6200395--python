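"""Shared fixtures: the default cell, its solved fixed point, and the
default virtual dendrite with its baseline steady state.

Session-scoped fixtures hold solved objects; tests that mutate state take
copies.
"""

import pytest

from pumpleak import make_default_cell, make_default_dendrite
from pumpleak.chain import solve_chain_steady_state
from pumpleak.steady import solve_steady_state


@pytest.fixture(scope="session")
def default_setup():
    """(state, params, bath) of the default 10 um x 25 um cell."""
    return make_default_cell()


@pytest.fixture(scope="session")
def default_steady(default_setup):
    """Solved fixed point of the default cell."""
    state, params, bath = default_setup
    return solve_steady_state(
        params, bath, state.pool.total_concentration * state.volume,
        state.pool.mean_charge, state.length)


@pytest.fixture(scope="session")
def dendrite_baseline():
    """(chain, baseline ChainSteadyState) of the default dendrite."""
    chain = make_default_dendrite()
    return chain, solve_chain_steady_state(chain)
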