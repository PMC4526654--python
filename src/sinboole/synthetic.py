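"""Seeded generators of random Boolean networks and corrupted fixtures.

These exist so every engine and scoring property is testable without any
external file: random networks exercise the attractor machinery against
brute-force oracles, and corrupted copies of a reference model (with the
edit log kept) drive recovery experiments for the scored hill-climber. The
random networks make no biological-realism claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .logic_core import And, BooleanExpression, BooleanNetwork, Const, Not, Or, Var
from .sin_model import (
    PhenotypeExpectation,
    SCORING_SET,
    enumerate_rule_edits,
)
from .experiments import ExperimentSpec, run_experiment

__all__ = [
    "RandomNetSpec",
    "random_network",
    "corrupt_model",
    "invert_edits",
    "EditLogEntry",
    "expectations_from_model",
]


@dataclass(frozen=True)
class RandomNetSpec:
    """Specification of a random Boolean network.

    ``n`` nodes, each with ``k`` distinct regulators drawn uniformly
    (``exact_k=False`` draws the in-degree uniformly from 0..k per node).
    ``rule_family`` is ``random_and_or_not`` (random AND/OR/NOT tree of depth
    ≤ 3 over the regulators, mirroring curated-rule structure) or
    ``random_truth_table`` (uniform truth table, rendered as a DNF). The same
    spec and seed always produce the identical network.
    """

    n: int
    k: int
    rule_family: str = "random_and_or_not"
    seed: int = 0
    exact_k: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.k < self.n:
            raise ValueError("require 0 <= k < n")
        if self.rule_family not in ("random_and_or_not", "random_truth_table"):
            raise ValueError(f"unknown rule family {self.rule_family!r}")


def _random_tree(
    rng: np.random.Generator, regulators: list[str], depth: int
) -> BooleanExpression:
    """Random AND/OR/NOT tree guaranteed to mention every regulator once the
    recursion bottoms out: leaves are drawn without replacement until the
    pool empties, then reused."""
    if not regulators:
        return Const(int(rng.integers(2)))

    pool = list(regulators)
    rng.shuffle(pool)

    def leaf() -> BooleanExpression:
        name = pool.pop() if pool else str(rng.choice(regulators))
        lit: BooleanExpression = Var(name)
        return Not(lit) if rng.integers(2) else lit

    def grow(d: int) -> BooleanExpression:
        if d == 0 or (not pool and rng.integers(2)):
            return leaf()
        op = And if rng.integers(2) else Or
        width = int(rng.integers(2, 4))
        return op([grow(d - 1) for _ in range(width)])

    expr = grow(depth)
    # fold in any regulator the random tree missed
    while pool:
        expr = (And if rng.integers(2) else Or)([expr, leaf()])
    return expr


def _dnf_from_truth_table(regulators: list[str], table: np.ndarray) -> BooleanExpression:
    """Render a truth table (LSB = first regulator) as a DNF expression."""
    if not regulators:
        return Const(int(table[0]))
    minterms = np.nonzero(table)[0]
    if len(minterms) == 0:
        return Const(0)
    if len(minterms) == len(table):
        return Const(1)
    terms: list[BooleanExpression] = []
    for m in minterms:
        lits: list[BooleanExpression] = []
        for j, reg in enumerate(regulators):
            lits.append(Var(reg) if (m >> j) & 1 else Not(Var(reg)))
        terms.append(lits[0] if len(lits) == 1 else And(lits))
    return terms[0] if len(terms) == 1 else Or(terms)


def random_network(spec: RandomNetSpec) -> BooleanNetwork:
    """Generate a validated random network per ``spec`` (seed-deterministic).

    Every node is regulated (no inputs); node names are ``n0..n{n-1}``.
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"n{i}" for i in range(spec.n)]
    rules: dict[str, BooleanExpression] = {}
    for i, name in enumerate(names):
        k = spec.k if spec.exact_k else int(rng.integers(0, spec.k + 1))
        others = [nm for j, nm in enumerate(names) if j != i]
        regs = sorted(rng.choice(others, size=k, replace=False).tolist()) if k else []
        if spec.rule_family == "random_and_or_not":
            rules[name] = _random_tree(rng, regs, depth=3)
        else:
            table = rng.integers(0, 2, size=1 << k)
            rules[name] = _dnf_from_truth_table(regs, table)
    return BooleanNetwork(tuple(names), frozenset(), rules, name=f"random_{spec.seed}")


# ---------------------------------------------------------------------------
# Corruption / recovery fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EditLogEntry:
    node: str
    old: BooleanExpression
    new: BooleanExpression


def corrupt_model(
    network: BooleanNetwork, n_edits: int, seed: int
) -> tuple[BooleanNetwork, list[EditLogEntry]]:
    """Apply ``n_edits`` random single-rule edits from the refinement move
    catalogue, sequentially. The log suffices to invert the corruption.

    Moves that leave the rule truth-table-equivalent (e.g. OR-ing in a
    redundant literal) are admissible — they are real moves in the catalogue —
    but each sampled move is drawn from the catalogue of the *current*
    network, so later edits can compound earlier ones.
    """
    if n_edits < 1:
        raise ValueError("n_edits must be >= 1")
    rng = np.random.default_rng(seed)
    current = network
    log: list[EditLogEntry] = []
    for _ in range(n_edits):
        moves = enumerate_rule_edits(current)
        node, new_expr = moves[int(rng.integers(len(moves)))]
        log.append(EditLogEntry(node, current.rules[node], new_expr))
        current = current.with_rule(node, new_expr)
    return current, log


def invert_edits(network: BooleanNetwork, log: list[EditLogEntry]) -> BooleanNetwork:
    """Undo a corruption by restoring the logged old rules in reverse order."""
    current = network
    for entry in reversed(log):
        current = current.with_rule(entry.node, entry.old)
    return current


def expectations_from_model(
    network: BooleanNetwork,
    specs: list[ExperimentSpec],
    scoring_nodes: tuple[str, ...] = SCORING_SET,
) -> list[PhenotypeExpectation]:
    """Ground-truth expectations: run each spec on ``network`` and record the
    summary labels of the scoring nodes. A model always scores perfectly
    against its own generated expectations."""
    rows: list[PhenotypeExpectation] = []
    for spec in specs:
        result = run_experiment(network, spec)
        expected = {n: result.summary[n] for n in scoring_nodes if n in result.summary}
        rows.append(
            PhenotypeExpectation(
                spec.experiment_id or spec.label(), spec.stage, spec.perturbations, expected
            )
        )
    return rows
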