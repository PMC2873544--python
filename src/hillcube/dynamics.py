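"""Synchronous Boolean dynamics: updates, steady states, STG, attractors.

All species apply their rules simultaneously; species without a rule keep
their value.  Exhaustive operations enumerate all 2^N states and are guarded
by a configurable limit.  States are reported as 0/1 tuples ordered like
``model.species``; the lexicographic order of tuples equals the numeric
order of the integer encoding used internally (species 0 = highest bit).
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .model import BooleanModel, ModelError

#: Largest N for which exhaustive 2^N enumeration is attempted by default.
ENUMERATION_LIMIT = 22

BooleanState = tuple[int, ...]


def synchronous_update(model: BooleanModel, state: BooleanState) -> BooleanState:
    """One synchronous step: x_i(t+1) = B_i(inputs at t); inputs unchanged."""
    if len(state) != model.n_species:
        raise ModelError(
            f"state length {len(state)} != {model.n_species} species"
        )
    env = dict(zip(model.species, state))
    nxt = []
    for name, value in zip(model.species, state):
        rule = model.rules.get(name)
        if rule is None:
            nxt.append(int(value))
        else:
            nxt.append(rule(tuple(env[i] for i in rule.inputs)))
    return tuple(nxt)


def _check_size(model: BooleanModel, limit: int) -> None:
    if model.n_species > limit:
        raise ModelError(
            f"model has {model.n_species} species; exhaustive enumeration is "
            f"limited to {limit} (2^N states)"
        )


def _successor_array(model: BooleanModel) -> np.ndarray:
    """Vectorized successor map over all 2^N integer-encoded states."""
    n = model.n_species
    states = np.arange(2**n, dtype=np.int64)
    bits = [(states >> (n - 1 - i)) & 1 for i in range(n)]
    index = {s: i for i, s in enumerate(model.species)}
    succ = np.zeros_like(states)
    for i, name in enumerate(model.species):
        rule = model.rules.get(name)
        if rule is None:
            value = bits[i]
        else:
            flat_idx = np.zeros_like(states)
            for inp in rule.inputs:
                flat_idx = (flat_idx << 1) | bits[index[inp]]
            value = rule.table.ravel()[flat_idx].astype(np.int64)
        succ |= value << (n - 1 - i)
    return succ


def _int_to_state(value: int, n: int) -> BooleanState:
    return tuple((value >> (n - 1 - i)) & 1 for i in range(n))


def boolean_steady_states(
    model: BooleanModel, limit: int = ENUMERATION_LIMIT
) -> list[BooleanState]:
    """All fixed points of the synchronous update, in lexicographic order."""
    _check_size(model, limit)
    succ = _successor_array(model)
    fixed = np.flatnonzero(succ == np.arange(succ.size))
    return [_int_to_state(int(v), model.n_species) for v in fixed]


def state_transition_graph(
    model: BooleanModel, limit: int = ENUMERATION_LIMIT
) -> nx.DiGraph:
    """Directed graph on all 2^N states with one edge per state to its
    synchronous successor (self-loops at fixed points)."""
    _check_size(model, limit)
    succ = _successor_array(model)
    n = model.n_species
    graph = nx.DiGraph()
    graph.add_nodes_from(_int_to_state(s, n) for s in range(succ.size))
    graph.add_edges_from(
        (_int_to_state(s, n), _int_to_state(int(t), n)) for s, t in enumerate(succ)
    )
    return graph


def synchronous_attractors(
    model: BooleanModel, limit: int = ENUMERATION_LIMIT
) -> list[list[BooleanState]]:
    """All terminal cycles of the STG, fixed points as length-1 cycles.

    Every state reaches exactly one attractor (out-degree 1).  Each cycle is
    rotated to start at its lexicographically smallest state; the attractor
    list is sorted by that state.
    """
    _check_size(model, limit)
    succ = _successor_array(model)
    n_states = succ.size
    # functional-graph cycle detection with three-color marking
    color = np.zeros(n_states, dtype=np.int8)  # 0 unseen, 1 on path, 2 done
    cycles: list[list[int]] = []
    for start in range(n_states):
        if color[start]:
            continue
        path: list[int] = []
        node = start
        while color[node] == 0:
            color[node] = 1
            path.append(node)
            node = int(succ[node])
        if color[node] == 1:  # found a new cycle; node is on the current path
            cyc = path[path.index(node):]
            cycles.append(cyc)
        for v in path:
            color[v] = 2
    n = model.n_species
    result = []
    for cyc in cycles:
        k = cyc.index(min(cyc))
        rotated = cyc[k:] + cyc[:k]
        result.append([_int_to_state(v, n) for v in rotated])
    result.sort(key=lambda c: c[0])
    return result


def attractor_basins(
    model: BooleanModel, limit: int = ENUMERATION_LIMIT
) -> dict[BooleanState, int]:
    """Map each state to the index (into :func:`synchronous_attractors`
    output) of the attractor it reaches."""
    _check_size(model, limit)
    succ = _successor_array(model)
    attractors = synchronous_attractors(model, limit)
    n = model.n_species
    label = np.full(succ.size, -1, dtype=np.int64)
    for idx, cyc in enumerate(attractors):
        for state in cyc:
            label[_state_to_int(state)] = idx
    for start in range(succ.size):
        path = []
        node = start
        while label[node] < 0:
            path.append(node)
            node = int(succ[node])
        for v in path:
            label[v] = label[node]
    return {_int_to_state(s, n): int(label[s]) for s in range(succ.size)}


def _state_to_int(state: BooleanState) -> int:
    value = 0
    for bit in state:
        value = (value << 1) | bit
    return value
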