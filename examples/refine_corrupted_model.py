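"""One mechanized refinement cycle.

Corrupts the reference model by one random rule edit, scores it against the
training expectations (wild type plus five knockouts, three stages, seven
scoring nodes = 126 cells), then lets the greedy single-edit hill-climber
repair it. A perfect 126/126 means every scoring-set label matches again.
"""

from sinboole import build_final_model, corrupt_model, expected_phenotypes, hill_climb, score_model

model = build_final_model()
expectations = expected_phenotypes()

corrupted, log = corrupt_model(model, n_edits=1, seed=2)
print(f"corrupted rule   {log[0].node} := {log[0].new.to_native()}")
print(f"original rule    {log[0].node} := {log[0].old.to_native()}")
print(f"score before     {score_model(corrupted, expectations).total}/126")

repaired, score = hill_climb(corrupted, expectations)
print(f"score after      {score.total}/126")
print(f"repaired rule    {log[0].node} := {repaired.rules[log[0].node].to_native()}")
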