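# Methods

## The model class

`sinboole` works with Boolean (logical) networks: each node `i` carries a
binary activation state and an update rule `f_i` — an AND/OR/NOT expression
over declared nodes, with the constants 0/1 allowed for clamped
simplifications. *Input* nodes carry no rule; their value is supplied by a
clamp. The semantics is the standard one for qualitative models of signaling
networks: a state is the total assignment, and the dynamics is generated by
rule disagreement.

Two update schemes are implemented.

- **Asynchronous (default).** A transition flips exactly one unclamped node
  whose rule disagrees with its current value. We generate *all* such
  transitions, so the state-transition graph (STG) contains every trajectory
  any update order could realize. This is the right semantics when reaction
  timescales are unknown and heterogeneous, as in the SIN, at the cost of
  nondeterministic trajectories; attractors, not paths, are the model output.
- **Synchronous.** All disagreeing nodes flip at once (out-degree ≤ 1).
  Provided for comparison; fixed points coincide between schemes (a
  property test enforces this), cyclic attractors generally do not.

**Attractors** are the terminal strongly-connected components of the STG —
sets of states closed under the dynamics with no escaping transition. A
fixed point is a singleton terminal SCC with no enabled update.

### Engine

The engine is an explicit-state one: the full clamp-consistent space (2^f
states for f unclamped nodes) is enumerated, each rule is evaluated once per
node vectorized over all states with numpy, and terminal SCCs come from
`scipy.sparse.csgraph.connected_components(connection='strong')`. An
explicit engine is easy to verify exhaustively — the test suite cross-checks
it against a naive mutual-reachability oracle on random networks — and is
ample for models of this scale; the state cap defaults to 22 free nodes
(2^22 ≈ 4.2M states; a 16-node model with stage clamps uses 2^11 = 2048).
Unclamped input nodes are explored as frozen free variables: both values
occur in the space, but no transition changes them. Everything is
deterministic — lexicographic node order from the model file, states indexed
by bit pattern, attractors sorted by minimal member state — so outputs are
byte-stable. Requesting a clamp on an unknown node, a non-binary clamp, or a
start state inconsistent with the clamps is an error, never a silent
override.

## The staged simulation protocol

CDK activity both gates mitotic entry and inhibits cytokinesis until
anaphase, so a single CDK node cannot represent "the stage of the cycle".
Instead three independent input switches encode CDK level — CDK-L
(interphase), CDK-H (early mitosis), CDK-0 (late mitosis) — exactly one of
which is clamped on per simulation, together with Ppc89 = 1 (the SPB–SIN
linker: the scaffold may assemble at any stage). Remaining inputs (Cdc42)
default to 0. The CDK nodes are controls, not regulated species: the model
loader enforces that they are inputs, i.e. have zero in-degree, and the
experiment layer refuses to perturb them.

Perturbation semantics follows the three classic modes: knock-out = clamp 0
for the whole simulation; over-expression = clamp 1 for the whole
simulation; initial-state = fix the start value only, then evolve freely.
For initial-state experiments the full clamp-consistent STG is still built,
and reporting is restricted to attractors reachable from some state matching
the initial constraints. Over-expression-as-clamp is the default for every
node; `run`'s caller can refuse specific nodes where over-expression is
known to act indirectly (none in the bundled model, so the default
deny-list is empty).

**Septation readout.** An experiment is *septating* iff some attractor state
has both terminal kinase complexes active: Sid1-Cdc14 = 1 ∧ Sid2-Mob1 = 1.
The conjunction matters: in early mitosis Sid2-Mob1 is activated through the
scaffold arm while Sid1-Cdc14 is CDK-inhibited, and such cells must not
septate. This readout reproduces every mutant verdict in the behavioral
constraint suite.

**Panel labeling.** When a late-mitosis experiment yields exactly two
attractors, the panel splits the row into `_old` (the attractor with the
GAP complex ON — the old spindle pole body keeps the Byr4-Cdc16 GAP and
stays dark) and `_new` (the septating, GAP-off state), falling back to
minimal-state order if GAP does not separate them.

## The bundled SIN model

The reference network has 16 nodes: 5 inputs (the CDK triplet, Ppc89,
Cdc42) and 11 regulated nodes. The rule file
(`src/sinboole/data/sin_final.rules`) annotates every rule with its
mechanistic justification; the load-bearing choices are:

- `Byr4 := NOT Cdc42 AND (CDK-L OR NOT Sid2_Mob1) AND NOT (CDK-H AND Plo1)`
  — interphase CDK sustains the GAP scaffold; high CDK and Plo1 jointly
  strip it at mitotic entry; once the SIN fires, Sid2-Mob1 feedback keeps it
  off; Cdc42 antagonizes its loading.
- `Cdc16 := NOT Fin1` with `Fin1 := CDK-H` — the NIMA-family kinase displaces
  the catalytic GAP subunit from the SPB in early mitosis, the control point
  that shuts the GAP off when CDK is high.
- `Sid1_Cdc14 := Cdc7 AND NOT CDK-H` and
  `Sid2_Mob1 := Sid1_Cdc14 OR (Cdc7 AND Cdc11 AND CDK-H)` — the cascade
  ordering Spg1 → Cdc7 → Sid1-Cdc14 → Sid2-Mob1, with the early-mitotic
  scaffold shortcut to Sid2-Mob1 and CDK inhibition of Sid1-Cdc14.

The edge list as such is not the contract; the **behavioral constraint
suite** is. Ten test-enforced assertions pin the model's stage-resolved
behavior: unique SIN-inactive interphase steady state with the GAP on;
unique early-mitosis state with Cdc16 off, Plo1/Spg1/Cdc7/Sid2-Mob1 on and
Sid1-Cdc14 off; exactly two late-mitosis steady states matching the old/new
SPB patterns, with the old one abolished by clamping GAP = 0; cdc11 KO never
septates; byr4 and cdc16 KOs septate in interphase; spg1 and cdc7 KOs fail
with Spg1 still on in the cdc7 KO; the cdc11+cdc16 and byr4+sid4 double KOs
do not septate; and Cdc7 over-expression rescues the spg1, cdc11 and sid4
knockouts. Any semantically equivalent rule set passes the same suite; any
behavioral regression fails it.

The **Nuc2 variant** (17 nodes) adds `Nuc2 := NOT Plo1` and strengthens the
GAP to `Byr4 AND Cdc16 AND (Nuc2 OR NOT Cdc7)`: Nuc2 stimulates GAP activity
outside mitosis, and without Nuc2 the GAP can only restrain a cascade that
has not yet fired. The variant's signature prediction — interphase
bistability under a Nuc2 knockout (one SIN-inactive state, one septating) —
is what made the link testable; the final model omits Nuc2 because the
in-vivo test came back negative and the model does not cover the M-G1
resetting window where Nuc2 genuinely acts.

## Scoring and refinement

A candidate model is scored against a table of expected phenotypes: for each
row (an experiment id, a stage, a perturbation list, and expected
ON/OFF/AMBIVALENT labels over the seven scoring-set nodes) the experiment is
run, the attractors are summarized, and matching labels are counted; the
total is the sum over rows (18 rows × 7 nodes = 126 for the bundled training
table). Aggregation by plain sum is the simplest monotone choice: removing
rows can never raise a total, a property the tests enforce.

The bundled training table covers the wild type and five knockouts (cdc11,
spg1, cdc16, byr4, cdc7) at all three stages. Its labels are frozen from the
certified reference model — legitimate precisely because that model's
behavior is pinned assertion-by-assertion by the constraint suite, so the
table is a restatement of certified behavior, not of anything the scorer is
later asked to discover.

One refinement move edits a single rule: delete one literal occurrence,
toggle one literal's negation, or add one absent declared node as a
top-level AND/OR literal. The enumeration is deterministic; for the
reference model it yields 347 candidates. `hill_climb` is greedy
first-best-improvement with a perfect-score short-circuit, bounded at 5
rounds by default — deliberately the mechanization of one expert refinement
cycle, not a global search (multi-edit spaces explode combinatorially and
the curation literature, not an optimizer, should arbitrate among
score-equivalent models). The recovery property — 20 seeded one-edit
corruptions all restored to a perfect score, with ≥18/20 scoring strictly
below perfect beforehand — is the refinement analogue of a
parameter-recovery study.

## Synthetic generators

`random_network` draws, per node, `k` distinct regulators uniformly and a
rule either as a random AND/OR/NOT tree of depth ≤ 3 that mentions every
chosen regulator (default; mirrors the shape of curated rules) or as a
uniform random truth table rendered as a DNF. All generators take explicit
seeds and are reproducible to the byte; no test depends on global RNG state.
These networks exercise the engine and scorer only — they emulate nothing
about real regulatory topology (no scale-free structure, no signed-balance
constraints), so engine tests passing on them certify the *algorithms*, not
any biological claim. Likewise `corrupt_model` samples edits from the same
move catalogue the refiner uses, with a log sufficient to invert the damage.

## Sizes, tolerances, degenerate inputs

The quantities this package reproduces are discrete counts and labels, so
there are no numerical tolerances anywhere: attractor counts, state
patterns and scores are compared exactly. Problem sizes are desk-scale by
construction — 2^11 states per staged SIN experiment, 2^8 for oracle
cross-checks (100 networks), 2^8 × 200 for scheme-independence, 20 seeds ×
~350 candidates × 18 experiments for the recovery study — chosen so the full
battery re-runs exhaustively rather than by sampling. Degenerate inputs are
defined rather than accidental: a network with zero free nodes has a
single-state STG and is its own fixed point; an empty expectation table
scores 0/0; `summarize` of an empty attractor list is an error; an empty
interaction table yields all-zero statistics.

## Known limitations

- No multivalued logic: graded CDK levels are emulated by the three-switch
  encoding, and SPB asymmetry by attractor multiplicity, not by per-SPB
  compartments.
- The M-G1 SIN resetting window and Etd1 are outside the model's scope.
- Asynchronous exploration returns *possible* steady states; which are
  realized in vivo depends on timing the Boolean abstraction discards.
- The explicit-state engine is exhaustive and simple, but exponential in
  free nodes; models beyond ~22 free nodes need a symbolic engine instead.
- The SBML-qual writer is export-only; models are exchanged losslessly via
  the native, BoolNet-style and JSON dialects.
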