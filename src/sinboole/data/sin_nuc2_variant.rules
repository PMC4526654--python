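# Nuc2 variant of the SIN model (17 nodes): adds the APC/C component Nuc2
# as an interphase stimulator of the Byr4-Cdc16 GAP towards the Cdc7-Spg1
# complex. Differs from the final model in one added node and one changed
# rule (GAP). Used to probe whether Nuc2 restrains septation in interphase.
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
Byr4 := NOT Cdc42 AND (CDK-L OR NOT Sid2_Mob1) AND NOT (CDK-H AND Plo1)  # as in the final model
Nuc2 := NOT Plo1  # Nuc2 acts outside mitosis, when polo kinase is off
GAP := Byr4 AND Cdc16 AND (Nuc2 OR NOT Cdc7)  # Nuc2 stimulates GAP activity; without it the GAP only restrains a not-yet-fired cascade
Spg1 := Cdc11 AND NOT GAP  # the GTPase signals from the Cdc11 scaffold unless the GAP switches it off
Cdc7 := Spg1  # Cdc7 kinase binds GTP-loaded Spg1
Sid1_Cdc14 := Cdc7 AND NOT CDK-H  # Sid1-Cdc14 recruitment requires Cdc7 and is blocked by high CDK
Sid2_Mob1 := Sid1_Cdc14 OR (Cdc7 AND Cdc11 AND CDK-H)  # terminal kinase complex
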