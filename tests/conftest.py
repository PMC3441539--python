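import numpy as np
import pytest

from nhejsim import (
    EndStatus,
    FragmentDistribution,
    SimParams,
    build_initial_state,
)


@pytest.fixture
def params():
    """Default parameters: a = k_f*n_E/V = 1, b = k_j/V = 1, k_r = 0.1."""
    return SimParams()


@pytest.fixture
def unit_params():
    """All unit rates, convenient for hand-computed propensities."""
    return SimParams(k_f=1.0, n_E=1, k_j=1.0, k_r=1.0, V=1.0)


@pytest.fixture
def two_short():
    """Two one-site fragments (30 bp each, L_min=20 <= 30 < L_c=42)."""
    return FragmentDistribution.from_lengths([30, 30])


@pytest.fixture
def short_long():
    return FragmentDistribution.from_lengths([30, 100])


@pytest.fixture
def two_long():
    return FragmentDistribution.from_lengths([100, 100])


@pytest.fixture
def three_mixed():
    return FragmentDistribution.from_lengths([30, 30, 100])


def make_state(dist, params):
    return build_initial_state(dist, params)


def bind_all(state):
    """Set every tracked end BOUND (bypassing kinetics, for fixture setup)."""
    for frag in state.fragments.values():
        frag.ends = [EndStatus.BOUND] * len(frag.ends)
    return state
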