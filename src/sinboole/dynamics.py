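"""State-transition graphs and exhaustive attractor detection.

Semantics
---------
A *network state* assigns 0/1 to every node. *Clamps* freeze a subset of
nodes (inputs, knock-outs, over-expressions) for the whole simulation: a
clamped node never changes along a transition, and only clamp-consistent
states are explored. Under the **asynchronous** scheme each transition flips
exactly one unclamped node, and only when that node's rule disagrees with its
current value — all such single-node updates are explored exhaustively, so
the state-transition graph (STG) contains every trajectory any update order
could realize. Under the **synchronous** scheme all disagreeing nodes flip at
once (out-degree ≤ 1).

An *attractor* is a terminal strongly-connected component of the STG: a set
of states closed under the dynamics with no escaping transition. A fixed
point (steady state) is a singleton attractor with no enabled update; fixed
points are the same under both schemes.

Implementation
--------------
The full clamp-consistent state space (2^f states for f free nodes, capped at
2^22) is enumerated explicitly. Rules are evaluated once per node, vectorized
over all states with numpy; strong components come from
``scipy.sparse.csgraph.connected_components``. Everything is deterministic:
states are indexed by their bit pattern and attractors are sorted by their
minimal member state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .logic_core import And, BooleanExpression, BooleanNetwork, Const, Not, Or, Var

__all__ = [
    "NetworkState",
    "Clamps",
    "Attractor",
    "TransitionGraph",
    "StateSpaceTooLarge",
    "ClampInconsistency",
    "DEFAULT_STATE_CAP",
    "async_successors",
    "sync_successor",
    "build_stg",
    "find_attractors",
    "find_fixed_points",
    "summarize",
    "reachable_attractors",
]

DEFAULT_STATE_CAP = 22  # max free nodes; 2^22 explicit states


class StateSpaceTooLarge(ValueError):
    """Raised when the number of unclamped nodes exceeds the configured cap."""


class ClampInconsistency(ValueError):
    """Raised when a state disagrees with the clamps, or clamps self-conflict."""


# ---------------------------------------------------------------------------
# States and clamps
# ---------------------------------------------------------------------------

class NetworkState(Mapping[str, int]):
    """Immutable, hashable total 0/1 assignment over a network's nodes.

    Backed by a shared node-order tuple plus a bit tuple, so large state sets
    stay cheap. Iteration follows the canonical node order; two states over
    the same node order compare by bit pattern (giving a stable "minimal
    state" for attractor sorting).
    """

    __slots__ = ("_nodes", "_bits")

    def __init__(self, nodes: Sequence[str], bits: Sequence[int]):
        if len(nodes) != len(bits):
            raise ValueError("nodes and bits differ in length")
        self._nodes = tuple(nodes)
        self._bits = tuple(1 if b else 0 for b in bits)

    @classmethod
    def from_dict(cls, network: BooleanNetwork, assignment: Mapping[str, int]) -> "NetworkState":
        missing = set(network.nodes) - set(assignment)
        if missing:
            raise KeyError(f"assignment missing node(s): {sorted(missing)}")
        return cls(network.nodes, [assignment[n] for n in network.nodes])

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def bits(self) -> tuple[int, ...]:
        return self._bits

    def __getitem__(self, node: str) -> int:
        try:
            return self._bits[self._nodes.index(node)]
        except ValueError:
            raise KeyError(node) from None

    def __iter__(self):
        return iter(self._nodes)

    def __len__(self) -> int:
        return len(self._nodes)

    def __hash__(self) -> int:
        return hash((self._nodes, self._bits))

    def __eq__(self, other: object) -> bool:
        if isinstance(other, NetworkState):
            return self._nodes == other._nodes and self._bits == other._bits
        if isinstance(other, Mapping):
            return dict(self) == dict(other)
        return NotImplemented

    def __lt__(self, other: "NetworkState") -> bool:
        return self._bits < other._bits

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self._nodes, self._bits))

    def __repr__(self) -> str:
        on = [n for n, b in zip(self._nodes, self._bits) if b]
        return f"NetworkState(ON={on})"


Clamps = Mapping[str, int]


def check_clamps(network: BooleanNetwork, clamps: Clamps) -> dict[str, int]:
    """Normalize clamps; reject unknown nodes and non-binary values."""
    norm: dict[str, int] = {}
    for node, value in clamps.items():
        if node not in set(network.nodes):
            raise ClampInconsistency(f"clamp on unknown node {node!r}")
        if value not in (0, 1):
            raise ClampInconsistency(f"clamp value for {node!r} must be 0 or 1, got {value!r}")
        if node in norm and norm[node] != value:
            raise ClampInconsistency(f"node {node!r} clamped to both 0 and 1")
        norm[node] = int(value)
    return norm


def _check_state(network: BooleanNetwork, state: Mapping[str, int], clamps: dict[str, int]) -> None:
    for node, value in clamps.items():
        if state[node] != value:
            raise ClampInconsistency(
                f"state has {node}={state[node]} but clamp requires {value}"
            )


# ---------------------------------------------------------------------------
# Single-state successor operations (reference semantics, tree evaluation)
# ---------------------------------------------------------------------------

def async_successors(
    state: Mapping[str, int], network: BooleanNetwork, clamps: Clamps | None = None
) -> set[NetworkState]:
    """All asynchronous successors: one per unclamped node whose rule
    disagrees with its current value. Empty set iff ``state`` is a fixed point."""
    clamps = check_clamps(network, clamps or {})
    _check_state(network, state, clamps)
    out: set[NetworkState] = set()
    bits = [state[n] for n in network.nodes]
    for i, node in enumerate(network.nodes):
        if node in clamps or node in network.inputs:
            continue
        new = network.rules[node].evaluate(state)
        if new != bits[i]:
            flipped = list(bits)
            flipped[i] = new
            out.add(NetworkState(network.nodes, flipped))
    return out


def sync_successor(
    state: Mapping[str, int], network: BooleanNetwork, clamps: Clamps | None = None
) -> NetworkState:
    """The unique synchronous image: every unclamped rule applied at once;
    clamped and input nodes copy through."""
    clamps = check_clamps(network, clamps or {})
    _check_state(network, state, clamps)
    bits = []
    for node in network.nodes:
        if node in clamps or node in network.inputs:
            bits.append(state[node])
        else:
            bits.append(network.rules[node].evaluate(state))
    return NetworkState(network.nodes, bits)


# ---------------------------------------------------------------------------
# Vectorized rule evaluation over the whole clamp-consistent space
# ---------------------------------------------------------------------------

def _eval_vector(expr: BooleanExpression, columns: dict[str, np.ndarray], n_states: int) -> np.ndarray:
    if isinstance(expr, Var):
        return columns[expr.name]
    if isinstance(expr, Const):
        return np.full(n_states, bool(expr.value))
    if isinstance(expr, Not):
        return ~_eval_vector(expr.child, columns, n_states)
    if isinstance(expr, And):
        acc = _eval_vector(expr.children[0], columns, n_states).copy()
        for c in expr.children[1:]:
            acc &= _eval_vector(c, columns, n_states)
        return acc
    if isinstance(expr, Or):
        acc = _eval_vector(expr.children[0], columns, n_states).copy()
        for c in expr.children[1:]:
            acc |= _eval_vector(c, columns, n_states)
        return acc
    raise TypeError(f"unknown expression type {type(expr)}")  # pragma: no cover


@dataclass(frozen=True)
class _Space:
    """Enumerated clamp-consistent state space with per-node next values."""

    network: BooleanNetwork
    clamps: Mapping[str, int]
    free: tuple[str, ...]          # updatable nodes, canonical order
    n_states: int
    current: np.ndarray            # (n_states, n_free) bool, bit j = (i >> j) & 1
    nxt: np.ndarray                # (n_states, n_free) bool, rule values
    disagree: np.ndarray           # current != nxt

    def state(self, index: int) -> NetworkState:
        nodes = self.network.nodes
        bits = []
        j = 0
        for node in nodes:
            if node in self.clamps:
                bits.append(self.clamps[node])
            else:
                bits.append((index >> j) & 1)
                j += 1
        return NetworkState(nodes, bits)

    def index_of(self, state: Mapping[str, int]) -> int:
        idx = 0
        for j, node in enumerate(self.free):
            if state[node]:
                idx |= 1 << j
        return idx


def _enumerate_space(
    network: BooleanNetwork, clamps: Clamps | None, cap: int = DEFAULT_STATE_CAP
) -> _Space:
    clamps = check_clamps(network, clamps or {})
    # unclamped inputs are explored as frozen free variables: both values
    # occur in the space but no transition ever changes them
    free = tuple(n for n in network.nodes if n not in clamps)
    if len(free) > cap:
        raise StateSpaceTooLarge(
            f"{len(free)} unclamped nodes exceed the cap of {cap} (2^{cap} states)"
        )
    n_states = 1 << len(free)
    idx = np.arange(n_states, dtype=np.int64)
    columns: dict[str, np.ndarray] = {}
    for j, node in enumerate(free):
        columns[node] = ((idx >> j) & 1).astype(bool)
    for node, value in clamps.items():
        columns[node] = np.full(n_states, bool(value))
    current = np.column_stack([columns[n] for n in free]) if free else np.zeros((1, 0), bool)
    nxt_cols = [
        columns[node] if node in network.inputs
        else _eval_vector(network.rules[node], columns, n_states)
        for node in free
    ]
    nxt = np.column_stack(nxt_cols) if free else np.zeros((1, 0), bool)
    return _Space(network, clamps, free, n_states, current, nxt, current != nxt)


def _async_edges(space: _Space) -> tuple[np.ndarray, np.ndarray]:
    """Source/target index arrays of the asynchronous STG (one flip per edge)."""
    rows, cols = np.nonzero(space.disagree)
    targets = rows ^ (np.int64(1) << cols.astype(np.int64))
    return rows.astype(np.int64), targets


def _sync_edges(space: _Space) -> tuple[np.ndarray, np.ndarray]:
    """Synchronous edges: each non-fixed state maps to its full image."""
    weights = np.int64(1) << np.arange(len(space.free), dtype=np.int64)
    images = space.nxt @ weights if len(space.free) else np.zeros(1, dtype=np.int64)
    images = images.astype(np.int64)
    idx = np.arange(space.n_states, dtype=np.int64)
    moved = images != idx
    return idx[moved], images[moved]


# ---------------------------------------------------------------------------
# Public graph/attractor API
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Attractor:
    """A terminal SCC of the STG. ``states`` are sorted; ``kind`` is
    ``fixed_point`` for a singleton with no enabled update, else ``cyclic``."""

    states: tuple[NetworkState, ...]
    kind: str

    @property
    def is_fixed_point(self) -> bool:
        return self.kind == "fixed_point"

    def __len__(self) -> int:
        return len(self.states)

    def node_values(self, node: str) -> set[int]:
        return {s[node] for s in self.states}


@dataclass(frozen=True)
class TransitionGraph:
    """Explicit STG over all clamp-consistent states.

    ``graph`` is a :class:`networkx.DiGraph` whose vertices are state indices
    (bit patterns over the free nodes, LSB = first free node); use
    :meth:`state_of` to decode. Kept index-based so a 2^20-state graph stays
    representable.
    """

    network: BooleanNetwork
    clamps: Mapping[str, int]
    mode: str
    free_nodes: tuple[str, ...]
    graph: nx.DiGraph
    _space: _Space

    @property
    def n_states(self) -> int:
        return self._space.n_states

    @property
    def n_transitions(self) -> int:
        return self.graph.number_of_edges()

    def state_of(self, index: int) -> NetworkState:
        return self._space.state(index)

    def index_of(self, state: Mapping[str, int]) -> int:
        return self._space.index_of(state)

    def states(self) -> Iterable[NetworkState]:
        return (self._space.state(i) for i in range(self.n_states))


def build_stg(
    network: BooleanNetwork,
    clamps: Clamps | None = None,
    mode: str = "asynchronous",
    cap: int = DEFAULT_STATE_CAP,
) -> TransitionGraph:
    """Build the full STG over every clamp-consistent state.

    ``mode`` is ``asynchronous`` (each edge flips one disagreeing node) or
    ``synchronous`` (each non-fixed state has exactly one outgoing edge).
    Construction is deterministic; raises :class:`StateSpaceTooLarge` when
    more than ``cap`` nodes are unclamped.
    """
    mode = _norm_mode(mode)
    space = _enumerate_space(network, clamps, cap)
    src, dst = _async_edges(space) if mode == "asynchronous" else _sync_edges(space)
    g = nx.DiGraph()
    g.add_nodes_from(range(space.n_states))
    g.add_edges_from(zip(src.tolist(), dst.tolist()))
    return TransitionGraph(network, dict(space.clamps), mode, space.free, g, space)


def _norm_mode(mode: str) -> str:
    aliases = {
        "async": "asynchronous",
        "asynchronous": "asynchronous",
        "sync": "synchronous",
        "synchronous": "synchronous",
    }
    try:
        return aliases[mode.lower()]
    except KeyError:
        raise ValueError(f"unknown update mode {mode!r}") from None


def _terminal_sccs(
    n_states: int, src: np.ndarray, dst: np.ndarray
) -> list[np.ndarray]:
    """Terminal strongly-connected components, each as a sorted index array."""
    adj = sparse.csr_matrix(
        (np.ones(len(src), dtype=np.int8), (src, dst)), shape=(n_states, n_states)
    )
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    # a component is terminal iff no edge leaves it
    leaving = labels[src] != labels[dst]
    non_terminal = np.zeros(n_comp, dtype=bool)
    np.logical_or.at(non_terminal, labels[src[leaving]], True)
    terminal_ids = np.nonzero(~non_terminal)[0]
    members: list[np.ndarray] = []
    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    bounds = np.searchsorted(sorted_labels, np.arange(n_comp + 1))
    for comp in terminal_ids:
        members.append(np.sort(order[bounds[comp]:bounds[comp + 1]]))
    members.sort(key=lambda m: int(m[0]))
    return members


def find_attractors(
    network: BooleanNetwork,
    clamps: Clamps | None = None,
    mode: str = "asynchronous",
    cap: int = DEFAULT_STATE_CAP,
) -> list[Attractor]:
    """All attractors of the clamp-consistent space: the terminal SCCs of the
    STG under the chosen update mode, sorted by minimal member state."""
    mode = _norm_mode(mode)
    space = _enumerate_space(network, clamps, cap)
    src, dst = _async_edges(space) if mode == "asynchronous" else _sync_edges(space)
    out: list[Attractor] = []
    fixed = ~space.disagree.any(axis=1)
    for members in _terminal_sccs(space.n_states, src, dst):
        states = tuple(space.state(int(i)) for i in members)
        kind = "fixed_point" if len(members) == 1 and fixed[members[0]] else "cyclic"
        out.append(Attractor(states, kind))
    return out


def find_fixed_points(
    network: BooleanNetwork,
    clamps: Clamps | None = None,
    cap: int = DEFAULT_STATE_CAP,
) -> list[NetworkState]:
    """All steady states: clamp-consistent states where every unclamped
    rule agrees with the current value. Update-mode independent."""
    space = _enumerate_space(network, clamps, cap)
    fixed_idx = np.nonzero(~space.disagree.any(axis=1))[0]
    return [space.state(int(i)) for i in fixed_idx]


def summarize(attractors: Sequence[Attractor]) -> dict[str, str]:
    """Per-node ON/OFF/AMBIVALENT over every state of every attractor.

    ON: the node is 1 in all attractor states; OFF: 0 in all; AMBIVALENT:
    both values occur (across states of one cyclic attractor or across
    alternative attractors).
    """
    if not attractors:
        raise ValueError("summarize requires at least one attractor")
    nodes = attractors[0].states[0].nodes
    summary: dict[str, str] = {}
    for node in nodes:
        values: set[int] = set()
        for att in attractors:
            values |= att.node_values(node)
        summary[node] = "ON" if values == {1} else "OFF" if values == {0} else "AMBIVALENT"
    return summary


def reachable_attractors(
    stg: TransitionGraph, attractors: Sequence[Attractor], initial: Mapping[str, int]
) -> list[Attractor]:
    """Attractors reachable in ``stg`` from any state matching the partial
    assignment ``initial`` (free nodes not named may start either way)."""
    for node, value in initial.items():
        if node in stg.clamps and stg.clamps[node] != value:
            raise ClampInconsistency(
                f"initial value {node}={value} conflicts with clamp {stg.clamps[node]}"
            )
    start = [
        i
        for i in range(stg.n_states)
        if all(stg.state_of(i)[n] == v for n, v in initial.items())
    ]
    reached: set[int] = set()
    for s in start:
        reached |= nx.descendants(stg.graph, s)
        reached.add(s)
    out = []
    for att in attractors:
        indices = {stg.index_of(s) for s in att.states}
        if indices & reached:
            out.append(att)
    return out
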