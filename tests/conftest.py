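import itertools

import numpy as np
import pytest

from hillcube import parse_boolean_equations


@pytest.fixture
def or_switch():
    """Mutual inhibitory switch with auto-activation, OR-combined inputs."""
    return parse_boolean_equations("X = X || ~Y\nY = Y || ~X")


@pytest.fixture
def and_switch():
    """Mutual inhibitory switch with auto-activation, AND-combined inputs."""
    return parse_boolean_equations("X = X && ~Y\nY = Y && ~X")


def brute_force_fixed_points(model):
    """Oracle: enumerate all 2^N states and keep those mapping to themselves."""
    from hillcube import synchronous_update

    out = []
    for state in itertools.product((0, 1), repeat=model.n_species):
        if synchronous_update(model, state) == state:
            out.append(state)
    return out


def brute_force_attractors(model, n_steps=None):
    """Oracle: iterate every state 2^N steps, then read off the cycle it sits
    on; independent of the STG cycle-detection path."""
    from hillcube import synchronous_update

    n = model.n_species
    if n_steps is None:
        n_steps = 2**n
    cycles = set()
    for state in itertools.product((0, 1), repeat=n):
        s = state
        for _ in range(n_steps):
            s = synchronous_update(model, s)
        # s is now on a terminal cycle; walk it once
        cyc = [s]
        nxt = synchronous_update(model, s)
        while nxt != s:
            cyc.append(nxt)
            nxt = synchronous_update(model, nxt)
        k = cyc.index(min(cyc))
        cycles.add(tuple(cyc[k:] + cyc[:k]))
    return sorted(cycles)


def random_rule(rng, d):
    """A random d-input truth-table rule over inputs v1..vd."""
    from hillcube import UpdateRule

    inputs = tuple(f"v{j + 1}" for j in range(d))
    table = rng.integers(0, 2, size=2**d, dtype=np.uint8)
    return UpdateRule("target", inputs, table)
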