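"""Does Nuc2 restrain septation in interphase?

The variant model keeps the hypothesized Nuc2 -> GAP stimulatory link. With
Nuc2 intact, interphase has a single SIN-inactive steady state; knocking
Nuc2 out makes the system bistable — one inactive state and one that
septates in interphase. That bistability is the testable in-vivo prediction
(which experiments ultimately rejected, so the final model omits Nuc2).
"""

from sinboole import build_nuc2_variant, run_experiment
from sinboole.experiments import ExperimentSpec, knockout

variant = build_nuc2_variant()
for label, perts in [("Nuc2 intact", ()), ("Nuc2 KO", (knockout("Nuc2"),))]:
    result = run_experiment(variant, ExperimentSpec("interphase", perts))
    states = [
        "septating" if s["Sid1_Cdc14"] and s["Sid2_Mob1"] else "SIN-inactive"
        for a in result.attractors
        for s in a.states
    ]
    print(f"{label}: {len(result.attractors)} steady state(s): {', '.join(states)}")
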