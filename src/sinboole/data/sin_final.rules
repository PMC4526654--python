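# Final SIN model, 16 nodes. Inputs: the three mutually exclusive CDK
# stage switches, the SPB linker Ppc89, and Cdc42 (environmental, default 0).
# Each rule carries its mechanistic justification as a trailing comment.
input CDK-L
input CDK-H
input CDK-0
input Ppc89
input Cdc42
Sid4 := Ppc89  # scaffold: Sid4 binds the SPB via the linker Ppc89
Cdc11 := Sid4  # scaffold: Cdc11 loads onto Sid4
Fin1 := CDK-H  # NIMA-family kinase Fin1 is active in early mitosis
Plo1 := CDK-H OR CDK-0  # polo kinase active throughout mitosis; CDK-H reinforces it
Cdc16 := NOT Fin1  # Fin1 displaces the GAP subunit Cdc16 from the SPB at mitotic entry
Byr4 := NOT Cdc42 AND (CDK-L OR NOT Sid2_Mob1) AND NOT (CDK-H AND Plo1)  # Cdc42 antagonizes Byr4 loading; interphase CDK sustains it; CDK and Plo1 jointly remove it in mitosis; Sid2-Mob1 feedback clears it once the SIN fires
GAP := Byr4 AND Cdc16  # bipartite GTPase-activating complex: Byr4 scaffolds catalytic Cdc16
Spg1 := Cdc11 AND NOT GAP  # the GTPase signals from the Cdc11 scaffold unless the GAP switches it off
Cdc7 := Spg1  # Cdc7 kinase binds GTP-loaded Spg1
Sid1_Cdc14 := Cdc7 AND NOT CDK-H  # Sid1-Cdc14 recruitment requires Cdc7 and is blocked by high CDK
Sid2_Mob1 := Sid1_Cdc14 OR (Cdc7 AND Cdc11 AND CDK-H)  # terminal kinase: normally via Sid1-Cdc14; in early mitosis scaffold-bound Cdc7 suffices
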