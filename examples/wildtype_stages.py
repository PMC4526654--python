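"""Wild-type SIN behavior across the cell cycle.

Runs the unperturbed reference model at each CDK stage and prints the
ON/OFF/AMBIVALENT panel. Expect one SIN-inactive steady state in interphase
(GAP on), one signaling-without-Sid1-Cdc14 state in early mitosis, and two
late-mitosis states mirroring the asymmetric old/new spindle pole bodies —
the new-SPB row is the only septating one.
"""

from sinboole import build_final_model, run_panel
from sinboole.experiments import wildtype_panel_specs

model = build_final_model()
panel = run_panel(model, wildtype_panel_specs())
print(panel.drop(columns=list(model.inputs)).T.to_string())
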