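"""The curated SIN model, its Nuc2 variant, and the scoring/refinement harness.

The bundled 16-node network is the executable reconstruction of the final,
optimized septation-initiation model: five input nodes (the three CDK stage
switches, the SPB linker Ppc89, and Cdc42) and eleven regulated nodes
covering the scaffold (Sid4, Cdc11), the Byr4-Cdc16 GAP and its controls
(Fin1, Plo1, Byr4, Cdc16, GAP), and the signaling cascade (Spg1, Cdc7,
Sid1-Cdc14, Sid2-Mob1). Each rule in the model file carries a one-line
mechanistic justification. The reconstruction is certified by a behavioral
constraint suite (see the test suite): unique SIN-inactive interphase and
early-mitosis steady states, the two asymmetric late-mitosis states (old/new
SPB), and the full panel of mutant septation verdicts.

Scoring follows the refinement protocol used to optimize the model: run a
set of staged knock-out experiments, summarize each outcome over the seven
scoring-set nodes (Sid4, Cdc11, GAP, Spg1, Cdc7, Sid2-Mob1, Sid1-Cdc14), and
count the nodes whose ON/OFF/AMBIVALENT label matches the expectation. The
single-edge edit enumerator and hill-climber mechanize one refinement cycle:
alter one literal of one rule (delete, negate, or add an absent regulator),
re-score, keep improvements.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import yaml

from .experiments import (
    ExperimentSpec,
    Perturbation,
    knockout,
    run_experiment,
)
from .logic_core import (
    And,
    BooleanExpression,
    BooleanNetwork,
    Not,
    Or,
    Var,
    parse_rules,
)

__all__ = [
    "SCORING_SET",
    "TRAINING_KNOCKOUTS",
    "PhenotypeExpectation",
    "ModelScore",
    "build_final_model",
    "build_nuc2_variant",
    "training_specs",
    "expected_phenotypes",
    "score_model",
    "enumerate_rule_edits",
    "enumerate_single_edge_edits",
    "hill_climb",
]

#: The seven nodes whose simulated states score a candidate model.
SCORING_SET = ("Sid4", "Cdc11", "GAP", "Spg1", "Cdc7", "Sid2_Mob1", "Sid1_Cdc14")

#: The five knockouts (by model node) used as the training set.
TRAINING_KNOCKOUTS = ("Cdc11", "Spg1", "Cdc16", "Byr4", "Cdc7")


def _load_rules(filename: str, name: str) -> BooleanNetwork:
    text = resources.files("sinboole.data").joinpath(filename).read_text(encoding="utf-8")
    return parse_rules(text, name=name)


def build_final_model() -> BooleanNetwork:
    """The bundled 16-node reference SIN network (validated, CDK nodes input-only)."""
    return _load_rules("sin_final.rules", "sin_final")


def build_nuc2_variant() -> BooleanNetwork:
    """The 17-node variant with the Nuc2 -> GAP stimulatory link retained.

    Differs from the final model in exactly one added node (Nuc2 := NOT Plo1)
    and one changed rule (GAP gains the ``Nuc2 OR NOT Cdc7`` conjunct). Under
    a Nuc2 knockout in interphase it yields two steady states — one
    SIN-inactive, one septating — the in-silico prediction that motivated
    testing (and ultimately dropping) an interphase role for Nuc2.
    """
    return _load_rules("sin_nuc2_variant.rules", "sin_nuc2_variant")


def synthetic_pkn_fixture() -> str:
    """A 3-row synthetic PKN table (TSV text) exercising the table schema."""
    return resources.files("sinboole.data").joinpath("pkn_synthetic_3row.tsv").read_text(
        encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Expectations and scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeExpectation:
    """Expected scoring-set labels for one staged experiment."""

    experiment_id: str
    stage: str
    perturbations: tuple[Perturbation, ...]
    expected: Mapping[str, str]  # scoring node -> ON | OFF | AMBIVALENT

    def __post_init__(self) -> None:
        object.__setattr__(self, "perturbations", tuple(self.perturbations))
        object.__setattr__(self, "expected", dict(self.expected))
        for node, label in self.expected.items():
            if label not in ("ON", "OFF", "AMBIVALENT"):
                raise ValueError(f"expected label for {node!r} must be ON/OFF/AMBIVALENT")

    def spec(self) -> ExperimentSpec:
        return ExperimentSpec(self.stage, self.perturbations, experiment_id=self.experiment_id)


@dataclass(frozen=True)
class ModelScore:
    """Matched-node counts per experiment row and in total."""

    per_experiment: Mapping[str, int]
    total: int
    max_total: int

    @property
    def perfect(self) -> bool:
        return self.total == self.max_total


def training_specs() -> list[ExperimentSpec]:
    """WT plus the five training knockouts, each at all three stages."""
    specs: list[ExperimentSpec] = []
    panels: list[tuple[str, tuple[Perturbation, ...]]] = [("WT", ())]
    panels += [(f"{node.lower()} KO", (knockout(node),)) for node in TRAINING_KNOCKOUTS]
    for exp_id, perts in panels:
        for stage in ("interphase", "early_mitosis", "late_mitosis"):
            specs.append(ExperimentSpec(stage, perts, experiment_id=exp_id))
    return specs


def expected_phenotypes() -> list[PhenotypeExpectation]:
    """The training expectation table: scoring-set labels for WT and the five
    training knockouts at each stage, as bundled in ``data/training.yaml``."""
    text = resources.files("sinboole.data").joinpath("training.yaml").read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    rows: list[PhenotypeExpectation] = []
    for row in doc["expectations"]:
        perts = tuple(
            Perturbation(p["node"], p["kind"], p.get("value")) for p in row.get("perturbations", [])
        )
        rows.append(
            PhenotypeExpectation(row["experiment"], row["stage"], perts, row["expected"])
        )
    return rows


def score_model(
    network: BooleanNetwork, expectations: Sequence[PhenotypeExpectation]
) -> ModelScore:
    """Score a candidate: per expectation row, simulate and count scoring-set
    nodes whose summary label matches. Total is the sum over rows."""
    missing = [n for n in SCORING_SET if n not in set(network.nodes)]
    if missing:
        raise ValueError(f"network lacks scoring-set node(s): {missing}")
    per: dict[str, int] = {}
    total = 0
    max_total = 0
    for row in expectations:
        result = run_experiment(network, row.spec())
        summary = result.summary
        matched = sum(
            1 for node, label in row.expected.items() if summary.get(node) == label
        )
        key = f"{row.experiment_id} [{row.stage}]"
        per[key] = matched
        total += matched
        max_total += len(row.expected)
    return ModelScore(per, total, max_total)


# ---------------------------------------------------------------------------
# Single-edge edit enumeration (one refinement move)
# ---------------------------------------------------------------------------

def _literal_paths(expr: BooleanExpression, path: tuple[int, ...] = ()) -> list[tuple[int, ...]]:
    """Paths to literal units (Var or Not(Var)), not descending into them."""
    if isinstance(expr, Var):
        return [path]
    if isinstance(expr, Not) and isinstance(expr.child, Var):
        return [path]
    if isinstance(expr, Not):
        return _literal_paths(expr.child, path + (0,))
    if isinstance(expr, (And, Or)):
        out: list[tuple[int, ...]] = []
        for i, c in enumerate(expr.children):
            out.extend(_literal_paths(c, path + (i,)))
        return out
    return []  # Const


def _replace_at(
    expr: BooleanExpression, path: tuple[int, ...], new: BooleanExpression | None
) -> BooleanExpression | None:
    """Rebuild with the subtree at ``path`` replaced (None = deleted)."""
    if not path:
        return new
    head, rest = path[0], path[1:]
    if isinstance(expr, Not):
        child = _replace_at(expr.child, rest, new)
        return None if child is None else Not(child)
    if isinstance(expr, (And, Or)):
        children: list[BooleanExpression] = []
        for i, c in enumerate(expr.children):
            if i == head:
                replaced = _replace_at(c, rest, new)
                if replaced is not None:
                    children.append(replaced)
            else:
                children.append(c)
        if not children:
            return None
        if len(children) == 1:
            return children[0]
        return And(children) if isinstance(expr, And) else Or(children)
    raise ValueError("path does not address a subtree")  # pragma: no cover


def _subtree_at(expr: BooleanExpression, path: tuple[int, ...]) -> BooleanExpression:
    for i in path:
        expr = expr.child if isinstance(expr, Not) else expr.children[i]
    return expr


def _toggle_literal(expr: BooleanExpression, path: tuple[int, ...]) -> BooleanExpression:
    unit = _subtree_at(expr, path)
    flipped = unit.child if isinstance(unit, Not) else Not(unit)
    return _replace_at(expr, path, flipped)  # type: ignore[return-value]


def enumerate_rule_edits(network: BooleanNetwork) -> list[tuple[str, BooleanExpression]]:
    """All single-rule edit moves, in deterministic order.

    For each regulated node's rule: every single-literal deletion, every
    single-literal negation toggle, and every addition of an absent declared
    node as a top-level AND or OR literal. Each move yields a (node,
    new expression) pair; applying any one of them changes exactly one rule.
    """
    moves: list[tuple[str, BooleanExpression]] = []
    declared = sorted(network.nodes)
    for node in network.nodes:
        if node in network.inputs:
            continue
        expr = network.rules[node]
        paths = _literal_paths(expr)
        for path in paths:
            deleted = _replace_at(expr, path, None)
            if deleted is not None and deleted != expr:
                moves.append((node, deleted))
        for path in paths:
            moves.append((node, _toggle_literal(expr, path)))
        present = expr.variables()
        for absent in declared:
            if absent in present:
                continue
            lit = Var(absent)
            conj = And(tuple(expr.children) + (lit,)) if isinstance(expr, And) else And([expr, lit])
            disj = Or(tuple(expr.children) + (lit,)) if isinstance(expr, Or) else Or([expr, lit])
            moves.append((node, conj))
            moves.append((node, disj))
    return moves


def enumerate_single_edge_edits(network: BooleanNetwork) -> list[BooleanNetwork]:
    """Candidate networks one edit move away from ``network`` (all validate)."""
    return [network.with_rule(node, expr) for node, expr in enumerate_rule_edits(network)]


def hill_climb(
    network: BooleanNetwork,
    expectations: Sequence[PhenotypeExpectation],
    max_rounds: int = 5,
) -> tuple[BooleanNetwork, ModelScore]:
    """Greedy single-edit refinement guided by :func:`score_model`.

    Each round scores every single-edge edit of the incumbent and moves to
    the best strict improvement (first in enumeration order on ties); a
    perfect score short-circuits the scan. Stops after ``max_rounds`` rounds
    or when no edit improves. This mechanizes one expert refinement cycle:
    alter an edge, simulate the perturbation panel, keep the model variant
    that best matches the expected phenotypes.
    """
    best = network
    best_score = score_model(network, expectations)
    for _ in range(max_rounds):
        if best_score.perfect:
            break
        round_best: BooleanNetwork | None = None
        round_score = best_score
        for candidate in enumerate_single_edge_edits(best):
            s = score_model(candidate, expectations)
            if s.total > round_score.total:
                round_best, round_score = candidate, s
                if s.perfect:
                    break
        if round_best is None:
            break
        best, best_score = round_best, round_score
    return best, best_score
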