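# sinboole

Boolean modeling of the fission-yeast **Septation Initiation Network**
(SIN) — the kinase cascade that triggers cytokinesis in
*Schizosaccharomyces pombe* once mitotic CDK activity falls. SIN failure
leaves elongated multinucleate cells; SIN hyperactivation septates cells
that are still in interphase. `sinboole` is a qualitative-modeling toolkit
for systems biologists who want to simulate this switch, and networks like
it, without kinetic parameters.

## What it computes

Each gene product is a node with state 1 (active) or 0 (inactive) and an
update rule `f_i` built from AND/OR/NOT over other nodes; a network state is
the vector `x ∈ {0,1}^n`. Under **asynchronous update** a transition flips
one node `i` with `f_i(x) ≠ x_i`; all such single-node updates are explored
exhaustively, giving the full state-transition graph over every
clamp-consistent state. An **attractor** is a terminal strongly-connected
component of that graph; a singleton with no enabled update is a steady
state. The engine enumerates all of them (vectorized rule evaluation +
sparse strong-component analysis, capped at 2^22 states).

On top of the engine:

- **Stage protocol.** Three mutually exclusive CDK input switches select the
  cell-cycle stage: CDK-L on = interphase, CDK-H on = early mitosis,
  CDK-0 on = late mitosis, with the SPB linker Ppc89 always on.
- **Perturbations.** Knock-out (clamp 0), over-expression (clamp 1), and
  initial-state experiments, alone or in combination; panels of experiments
  are summarized per node as ON / OFF / AMBIVALENT.
- **The curated SIN model.** A bundled 16-node reference network (and a
  17-node Nuc2 variant), certified by a behavioral test suite covering the
  stage-resolved wild-type steady states and a panel of mutant phenotypes.
- **Scoring & refinement.** Candidate models are scored by how many of seven
  scoring-set nodes (Sid4, Cdc11, GAP, Spg1, Cdc7, Sid2-Mob1, Sid1-Cdc14)
  match expected labels across a training panel; a single-edge edit
  enumerator plus greedy hill-climber mechanizes one refinement cycle.
- **Interchange.** Native rule files, BoolNet-style `targets, factors`
  tables, a JSON schema (all round-trip), SBML-qual export, and the curated
  prior-knowledge-network TSV schema with signed-digraph extraction.
- **Synthetic fixtures.** Seeded random Boolean networks and seeded
  model corruptions with invertible edit logs, for engine- and
  refinement-level testing.

## Worked example

```python
from sinboole import build_final_model, run_experiment
from sinboole.experiments import ExperimentSpec, knockout, overexpression

model = build_final_model()

wt = run_experiment(model, ExperimentSpec("late_mitosis"))
print(len(wt.attractors), wt.septation)

rescue = run_experiment(model, ExperimentSpec(
    "late_mitosis", (knockout("Sid4"), overexpression("Cdc7"))))
print(len(rescue.attractors), rescue.septation)
```

prints

```
2 septating
1 septating
```

The wild-type late-mitosis simulation has exactly **two** steady states —
the model's readout of the asymmetric old/new spindle-pole bodies of late
anaphase: in one the Byr4-Cdc16 GAP is assembled and the cascade is dark; in
the other the GAP is gone and Spg1, Cdc7, Sid1-Cdc14 and Sid2-Mob1 all fire
(that state septates). The second experiment is the counter-intuitive
scaffold bypass: without Sid4 the SPB scaffold cannot assemble, yet clamping
Cdc7 on still drives septation. More narrative walk-throughs live in
`examples/` (one script per capability), and a thin CLI mirrors them:
`sinboole run --stage lM --ko Sid4 --oe Cdc7`,
`sinboole attractors sin --clamp CDK-0=1 ...`, `sinboole panel`,
`sinboole pkn stats <tsv>`, `sinboole synth net --n 10 --k 2 --seed 7`.

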