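"""Knock-out / over-expression panel of SIN mutants.

Reproduces the classic in-silico mutant verdicts: scaffold knockouts block
septation, GAP-subunit knockouts fire the SIN already in interphase, and
over-expressed Cdc7 drives septation even without the Sid4/Cdc11 scaffold
(the counter-intuitive rescue that was validated in vivo).
"""

from sinboole import build_final_model, run_experiment
from sinboole.experiments import ExperimentSpec, knockout, overexpression

model = build_final_model()
experiments = [
    ("cdc11 KO", "late_mitosis", (knockout("Cdc11"),)),
    ("byr4 KO", "interphase", (knockout("Byr4"),)),
    ("cdc16 KO", "interphase", (knockout("Cdc16"),)),
    ("spg1 KO", "late_mitosis", (knockout("Spg1"),)),
    ("cdc11 + cdc16 KO", "late_mitosis", (knockout("Cdc11"), knockout("Cdc16"))),
    ("byr4 + sid4 KO", "late_mitosis", (knockout("Byr4"), knockout("Sid4"))),
    ("spg1 KO + cdc7 OE", "late_mitosis", (knockout("Spg1"), overexpression("Cdc7"))),
    ("cdc11 KO + cdc7 OE", "late_mitosis", (knockout("Cdc11"), overexpression("Cdc7"))),
    ("sid4 KO + cdc7 OE", "late_mitosis", (knockout("Sid4"), overexpression("Cdc7"))),
]
for label, stage, perts in experiments:
    result = run_experiment(model, ExperimentSpec(stage, perts, experiment_id=label))
    print(f"{result.spec.label():35s} {len(result.attractors)} attractor(s)  {result.septation}")
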