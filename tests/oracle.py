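"""Independent brute-force attractor oracle for cross-checking the engine.

Deliberately naive and structurally unrelated to the library's vectorized
state-transition-graph / strong-component implementation: states are plain
dicts, successors come from per-state expression-tree evaluation, and an
attractor is found from first principles — a state belongs to an attractor
iff every state reachable from it can reach it back (mutual reachability),
and the attractor is the closure of such a state.
"""

from __future__ import annotations

from itertools import product

from sinboole.logic_core import BooleanNetwork


def _states(network: BooleanNetwork, clamps: dict[str, int]):
    free = [n for n in network.nodes if n not in clamps]
    for bits in product((0, 1), repeat=len(free)):
        state = dict(clamps)
        state.update(zip(free, bits))
        yield tuple(state[n] for n in network.nodes)


def _successors(network: BooleanNetwork, clamps: dict[str, int], state: tuple, mode: str):
    as_dict = dict(zip(network.nodes, state))
    updatable = [
        (i, n)
        for i, n in enumerate(network.nodes)
        if n not in clamps and n not in network.inputs
    ]
    if mode == "asynchronous":
        out = []
        for i, n in updatable:
            v = network.rules[n].evaluate(as_dict)
            if v != state[i]:
                succ = list(state)
                succ[i] = v
                out.append(tuple(succ))
        return out
    succ = list(state)
    for i, n in updatable:
        succ[i] = network.rules[n].evaluate(as_dict)
    return [tuple(succ)] if tuple(succ) != state else []


def _reach(succ_map: dict, start: tuple) -> set:
    seen = {start}
    frontier = [start]
    while frontier:
        s = frontier.pop()
        for t in succ_map[s]:
            if t not in seen:
                seen.add(t)
                frontier.append(t)
    return seen


def oracle_attractors(
    network: BooleanNetwork, clamps: dict[str, int] | None = None, mode: str = "asynchronous"
) -> list[frozenset]:
    """All attractors as frozensets of full-state tuples (node order =
    network.nodes), sorted by minimal member for determinism."""
    clamps = clamps or {}
    succ_map = {s: _successors(network, clamps, s, mode) for s in _states(network, clamps)}
    reach = {s: _reach(succ_map, s) for s in succ_map}
    attractors: set[frozenset] = set()
    for s in succ_map:
        if all(s in reach[t] for t in reach[s]):
            attractors.add(frozenset(reach[s]))
    return sorted(attractors, key=lambda a: min(a))


def oracle_fixed_points(network: BooleanNetwork, clamps: dict[str, int] | None = None):
    clamps = clamps or {}
    return sorted(
        s
        for s in _states(network, clamps)
        if not _successors(network, clamps, s, "asynchronous")
    )
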