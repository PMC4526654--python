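"""Staged in-silico perturbation experiments.

The cell-cycle stage is selected through three mutually exclusive CDK input
nodes — CDK-L (low interphase activity), CDK-H (high early-mitotic activity)
and CDK-0 (near-zero activity in late mitosis) — plus the SPB linker Ppc89,
clamped on in every stage so the SIN scaffold can always assemble:

========== ====== ====== ====== ======
stage       CDK-L  CDK-H  CDK-0  Ppc89
interphase    1      0      0      1
early_mitosis 0      1      0      1
late_mitosis  0      0      1      1
========== ====== ====== ====== ======

Any other input node of the model defaults to 0 (in the reference model,
Cdc42). The CDK nodes are pure controls: they have no incoming regulation
(validated at load) and may not themselves be perturbed.

Perturbations follow the three classic simulation modes: a *knockout* clamps
the node to 0 for the whole simulation, an *over-expression* clamps it to 1,
and an *initial_state* perturbation fixes the node's starting value only,
after which it evolves freely (reporting is then restricted to attractors
reachable from the matching start states).

The phenotype readout is binary: an experiment is *septating* iff some
attractor state has both terminal kinase complexes, Sid1-Cdc14 and
Sid2-Mob1, active at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dynamics import (
    Attractor,
    build_stg,
    find_attractors,
    reachable_attractors,
    summarize,
)
from .logic_core import BooleanNetwork

__all__ = [
    "STAGES",
    "CDK_NODES",
    "Perturbation",
    "knockout",
    "overexpression",
    "initial_state",
    "ExperimentSpec",
    "ExperimentResult",
    "stage_clamps",
    "apply_perturbations",
    "run_experiment",
    "run_panel",
    "septation_readout",
    "validate_stage_inputs",
]

CDK_NODES = ("CDK-L", "CDK-H", "CDK-0")
SCAFFOLD_LINKER = "Ppc89"
SEPTATION_NODES = ("Sid1_Cdc14", "Sid2_Mob1")

_STAGE_CDK = {
    "interphase": {"CDK-L": 1, "CDK-H": 0, "CDK-0": 0},
    "early_mitosis": {"CDK-L": 0, "CDK-H": 1, "CDK-0": 0},
    "late_mitosis": {"CDK-L": 0, "CDK-H": 0, "CDK-0": 1},
}
STAGES = tuple(_STAGE_CDK)
_STAGE_SHORT = {"interphase": "i", "early_mitosis": "eM", "late_mitosis": "lM"}


@dataclass(frozen=True)
class Perturbation:
    """A single node perturbation.

    ``kind`` is ``knockout`` (clamp 0), ``overexpression`` (clamp 1) or
    ``initial_state`` (start at ``value``, then free).
    """

    node: str
    kind: str
    value: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("knockout", "overexpression", "initial_state"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "initial_state":
            if self.value not in (0, 1):
                raise ValueError("initial_state perturbation requires value 0 or 1")
        elif self.value is not None:
            raise ValueError(f"{self.kind} takes no value (it is implied)")

    @property
    def clamp_value(self) -> int | None:
        if self.kind == "knockout":
            return 0
        if self.kind == "overexpression":
            return 1
        return None

    def label(self) -> str:
        tag = {"knockout": "KO", "overexpression": "OE", "initial_state": "init"}[self.kind]
        if self.kind == "initial_state":
            return f"{tag} {self.node}={self.value}"
        return f"{tag} {self.node}"


def knockout(node: str) -> Perturbation:
    return Perturbation(node, "knockout")


def overexpression(node: str) -> Perturbation:
    return Perturbation(node, "overexpression")


def initial_state(node: str, value: int) -> Perturbation:
    return Perturbation(node, "initial_state", value)


@dataclass(frozen=True)
class ExperimentSpec:
    """Stage + perturbation list for one simulation run."""

    stage: str
    perturbations: tuple[Perturbation, ...] = ()
    model_id: str = ""
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if self.stage not in _STAGE_CDK:
            raise ValueError(f"unknown stage {self.stage!r}; choose from {STAGES}")
        object.__setattr__(self, "perturbations", tuple(self.perturbations))
        seen: set[str] = set()
        for p in self.perturbations:
            if p.node in CDK_NODES:
                raise ValueError(
                    f"{p.node} is a stage-control node and cannot be perturbed"
                )
            if p.node in seen:
                raise ValueError(f"node {p.node!r} appears in more than one perturbation")
            seen.add(p.node)

    def label(self) -> str:
        base = self.experiment_id or (
            " + ".join(p.label() for p in self.perturbations) or "WT"
        )
        return f"{base} ({_STAGE_SHORT[self.stage]})"


@dataclass(frozen=True)
class ExperimentResult:
    spec: ExperimentSpec
    attractors: tuple[Attractor, ...]
    summary: Mapping[str, str]
    septation: str  # "septating" | "non_septating"

    @property
    def septating(self) -> bool:
        return self.septation == "septating"

    @property
    def n_steady_states(self) -> int:
        return sum(1 for a in self.attractors if a.is_fixed_point)


def stage_clamps(stage: str, network: BooleanNetwork | None = None) -> dict[str, int]:
    """Clamp pattern for a cell-cycle stage.

    The CDK triplet encodes the stage, Ppc89 is always on, and — when a
    network is given — every remaining input node defaults to 0 (the model's
    declared default for environmental inputs such as Cdc42).
    """
    if stage not in _STAGE_CDK:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    clamps = dict(_STAGE_CDK[stage])
    clamps[SCAFFOLD_LINKER] = 1
    if network is not None:
        declared = set(network.nodes)
        clamps = {n: v for n, v in clamps.items() if n in declared}
        for node in network.nodes:
            if node in network.inputs and node not in clamps:
                clamps[node] = 0
    return clamps


def apply_perturbations(
    clamps: Mapping[str, int], perturbations: Iterable[Perturbation]
) -> tuple[dict[str, int], dict[str, int]]:
    """Merge perturbations into stage clamps.

    Returns ``(clamps, initial)``: KO/OE extend the clamp map; initial-state
    perturbations go into the separate ``initial`` partial assignment.
    Clashes (perturbing a CDK node, contradicting an existing clamp, or two
    perturbations on one node) raise ``ValueError``.
    """
    merged = dict(clamps)
    initial: dict[str, int] = {}
    seen: set[str] = set()
    for p in perturbations:
        if p.node in CDK_NODES:
            raise ValueError(f"{p.node} is a stage-control node and cannot be perturbed")
        if p.node in seen:
            raise ValueError(f"contradictory perturbations on node {p.node!r}")
        seen.add(p.node)
        if p.kind == "initial_state":
            if p.node in merged and merged[p.node] != p.value:
                raise ValueError(
                    f"initial value {p.node}={p.value} conflicts with clamp {merged[p.node]}"
                )
            initial[p.node] = int(p.value)  # type: ignore[arg-type]
        else:
            value = p.clamp_value
            if p.node in merged and merged[p.node] != value:
                raise ValueError(
                    f"perturbation {p.label()} conflicts with existing clamp "
                    f"{p.node}={merged[p.node]}"
                )
            merged[p.node] = value  # type: ignore[assignment]
    return merged, initial


def validate_stage_inputs(network: BooleanNetwork) -> None:
    """Check the stage-protocol preconditions on a model: the CDK nodes it
    declares must be inputs (zero in-degree — nothing regulates the stage)."""
    declared = set(network.nodes)
    for node in CDK_NODES:
        if node not in declared:
            continue
        # input status is exactly "zero in-degree": inputs carry no rule,
        # so nothing in the model can regulate them
        if node not in network.inputs:
            raise ValueError(f"stage-control node {node} must be an input (it has a rule)")


def septation_readout(attractors: Sequence[Attractor]) -> str:
    """``septating`` iff some attractor state has Sid1_Cdc14=1 and Sid2_Mob1=1.

    Rationale: septum formation requires the most-downstream kinase
    Sid2-Mob1 to fire with its upstream activator Sid1-Cdc14 engaged; the
    early-mitotic state where Sid2-Mob1 is scaffold-activated while
    Sid1-Cdc14 is CDK-inhibited does not septate.
    """
    for att in attractors:
        for state in att.states:
            if all(state.get(n, 0) == 1 for n in SEPTATION_NODES):
                return "septating"
    return "non_septating"


def run_experiment(
    network: BooleanNetwork, spec: ExperimentSpec, mode: str = "asynchronous"
) -> ExperimentResult:
    """Run one staged experiment: clamp, explore exhaustively, summarize.

    Attractors come from exhaustive asynchronous exploration of the whole
    clamp-consistent space. If the spec carries initial-state perturbations,
    only attractors reachable from a matching start state are reported.
    """
    validate_stage_inputs(network)
    clamps, initial = apply_perturbations(stage_clamps(spec.stage, network), spec.perturbations)
    unknown = [n for n in clamps if n not in set(network.nodes)]
    if unknown:
        raise ValueError(f"perturbed/clamped node(s) not in model: {unknown}")
    attractors = find_attractors(network, clamps, mode)
    if initial:
        stg = build_stg(network, clamps, mode)
        attractors = reachable_attractors(stg, attractors, initial)
    summary = summarize(attractors) if attractors else {}
    return ExperimentResult(spec, tuple(attractors), summary, septation_readout(attractors))


def _gap_active(att: Attractor, gap_node: str = "GAP") -> bool:
    return att.node_values(gap_node) == {1} if gap_node in att.states[0].nodes else False


def run_panel(
    network: BooleanNetwork,
    specs: Sequence[ExperimentSpec],
    mode: str = "asynchronous",
) -> pd.DataFrame:
    """Run a suite of experiments and tabulate per-node outcomes.

    One row per experiment (index = spec label), one column per model node
    plus a ``septation`` column; cells are ON/OFF/AMBIVALENT. A late-mitosis
    result with exactly two attractors is split into ``_new``/``_old`` rows —
    the GAP-active attractor is ``_old`` (the SPB that keeps the
    Byr4-Cdc16 GAP and stays SIN-inactive), the other ``_new``.
    """
    if not specs:
        raise ValueError("run_panel requires at least one experiment spec")
    rows: list[dict[str, str]] = []
    index: list[str] = []
    for spec in specs:
        result = run_experiment(network, spec, mode)
        split = (
            spec.stage == "late_mitosis"
            and len(result.attractors) == 2
            and "GAP" in network.nodes
        )
        if split:
            old = [a for a in result.attractors if _gap_active(a)]
            new = [a for a in result.attractors if not _gap_active(a)]
            if len(old) == 1 and len(new) == 1:
                pairs = [("_new", new[0]), ("_old", old[0])]
            else:  # tie-break by minimal-state order when GAP does not separate
                pairs = list(zip(("_new", "_old"), result.attractors))
            for suffix, att in pairs:
                row = dict(summarize([att]))
                row["septation"] = septation_readout([att])
                rows.append(row)
                index.append(spec.label() + suffix)
            continue
        row = dict(result.summary)
        row["septation"] = result.septation
        rows.append(row)
        index.append(spec.label())
    return pd.DataFrame(rows, index=index, columns=list(network.nodes) + ["septation"])


def wildtype_panel_specs() -> list[ExperimentSpec]:
    """The three unperturbed stage simulations."""
    return [ExperimentSpec(stage) for stage in STAGES]
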