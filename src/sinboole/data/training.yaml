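# Training expectation table: scoring-set labels for the wild type and the
# five training knockouts (cdc11, spg1, cdc16, byr4, cdc7) at each cell-cycle
# stage. Frozen from the certified reference model, whose stage/mutant
# behavior is pinned, steady state by steady state, by the behavioral
# constraint test suite.
scoring_set:
- Sid4
- Cdc11
- GAP
- Spg1
- Cdc7
- Sid2_Mob1
- Sid1_Cdc14
expectations:
- experiment: WT
  stage: interphase
  perturbations: []
  expected:
    Sid4: 'ON'
    Cdc11: 'ON'
    GAP: 'ON'
    Spg1: 'OFF'
    Cdc7: 'OFF'
    Sid2_Mob1: 'OFF'
    Sid1_Cdc14: 'OFF'
- experiment: WT
  stage: early_mitosis
  perturbations: []
  expected:
    Sid4: 'ON'
    Cdc11: 'ON'
    GAP: 'OFF'
    Spg1: 'ON'
    Cdc7: 'ON'
    Sid2_Mob1: 'ON'
    Sid1_Cdc14: 'OFF'
- experiment: WT
  stage: late_mitosis
  perturbations: []
  expected:
    Sid4: 'ON'
    Cdc11: 'ON'
    GAP: AMBIVALENT
    Spg1: AMBIVALENT
    Cdc7: AMBIVALENT
    Sid2_Mob1: AMBIVALENT
    Sid1_Cdc14: AMBIVALENT
- experiment: cdc11 KO
  stage: interphase
  perturbations:
  - node: Cdc11
    kind: knockout
  expected:
    Sid4: 'ON'
    Cdc11: 'OFF'
    GAP: 'ON'
    Spg1: 'OFF'
    Cdc7: 'OFF'
    Sid2_Mob1: 'OFF'
    Sid1_Cdc14: 'OFF'
- experiment: cdc11 KO
  stage: early_mitosis
  perturbations:
  - node: Cdc11
    kind: knockout
  expected:
    Sid4: 'ON'
    Cdc11: 'OFF'
    GAP: 'OFF'
    Spg1: 'OFF'
    Cdc7: 'OFF'
    Sid2_Mob1: 'OFF'
    Sid1_Cdc14: 'OFF'
- experiment: cdc11 KO
  stage: late_mitosis
  perturbations:
  - node: Cdc11
    kind: knockout
  expected:
    Sid4: 'ON'
    Cdc11: 'OFF'
    GAP: 'ON'
    Spg1: 'OFF'
    Cdc7: 'OFF'
    Sid2_Mob1: 'OFF'
    Sid1_Cdc14: 'OFF'
- experiment: spg1 KO
  stage: interphase
  perturbations:
  - node: Spg1
    kind: knockout
  expected:
    Sid4: 'ON'
    Cdc11: 'ON'
    GAP: 'ON'
    Spg1: 'OFF'
    Cdc7: 'OFF'
    Sid2_Mob1: 'OFF'
    Sid1_Cdc14: 'OFF'
- experiment: spg1 KO
  stage: early_mitosis
  perturbations:
  - node: Spg1
    kind: knockout
  expected:
    Sid4: 'ON'
    Cdc11: 'ON'
    GAP: 'OFF'
    Spg1: 'OFF'
    Cdc7: 'OFF'
    Sid2_Mob1: 'OFF'
    Sid1_Cdc14: 'OFF'
- experiment: spg1 KO
  stage: late_mitosis
  perturbations:
  - node: Spg1
    kind: knockout
  expected:
    Sid4: 'ON'
    Cdc11: 'ON'
    GAP: 'ON'
    Spg1: 'OFF'
    Cdc7: 'OFF'
    Sid2_Mob1: 'OFF'
    Sid1_Cdc14: 'OFF'
- experiment: cdc16 KO
  stage: interphase
  perturbations:
  - node: Cdc16
    kind: knockout
  expected:
    Sid4: 'ON'
    Cdc11: 'ON'
    GAP: 'OFF'
    Spg1: 'ON'
    Cdc7: 'ON'
    Sid2_Mob1: 'ON'
    Sid1_Cdc14: 'ON'
- experiment: cdc16 KO
  stage: early_mitosis
  perturbations:
  - node: Cdc16
    kind: knockout
  expected:
    Sid4: 'ON'
    Cdc11: 'ON'
    GAP: 'OFF'
    Spg1: 'ON'
    Cdc7: 'ON'
    Sid2_Mob1: 'ON'
    Sid1_Cdc14: 'OFF'
- experiment: cdc16 KO
  stage: late_mitosis
  perturbations:
  - node: Cdc16
    kind: knockout
  expected:
    Sid4: 'ON'
    Cdc11: 'ON'
    GAP: 'OFF'
    Spg1: 'ON'
    Cdc7: 'ON'
    Sid2_Mob1: 'ON'
    Sid1_Cdc14: 'ON'
- experiment: byr4 KO
  stage: interphase
  perturbations:
  - node: Byr4
    kind: knockout
  expected:
    Sid4: 'ON'
    Cdc11: 'ON'
    GAP: 'OFF'
    Spg1: 'ON'
    Cdc7: 'ON'
    Sid2_Mob1: 'ON'
    Sid1_Cdc14: 'ON'
- experiment: byr4 KO
  stage: early_mitosis
  perturbations:
  - node: Byr4
    kind: knockout
  expected:
    Sid4: 'ON'
    Cdc11: 'ON'
    GAP: 'OFF'
    Spg1: 'ON'
    Cdc7: 'ON'
    Sid2_Mob1: 'ON'
    Sid1_Cdc14: 'OFF'
- experiment: byr4 KO
  stage: late_mitosis
  perturbations:
  - node: Byr4
    kind: knockout
  expected:
    Sid4: 'ON'
    Cdc11: 'ON'
    GAP: 'OFF'
    Spg1: 'ON'
    Cdc7: 'ON'
    Sid2_Mob1: 'ON'
    Sid1_Cdc14: 'ON'
- experiment: cdc7 KO
  stage: interphase
  perturbations:
  - node: Cdc7
    kind: knockout
  expected:
    Sid4: 'ON'
    Cdc11: 'ON'
    GAP: 'ON'
    Spg1: 'OFF'
    Cdc7: 'OFF'
    Sid2_Mob1: 'OFF'
    Sid1_Cdc14: 'OFF'
- experiment: cdc7 KO
  stage: early_mitosis
  perturbations:
  - node: Cdc7
    kind: knockout
  expected:
    Sid4: 'ON'
    Cdc11: 'ON'
    GAP: 'OFF'
    Spg1: 'ON'
    Cdc7: 'OFF'
    Sid2_Mob1: 'OFF'
    Sid1_Cdc14: 'OFF'
- experiment: cdc7 KO
  stage: late_mitosis
  perturbations:
  - node: Cdc7
    kind: knockout
  expected:
    Sid4: 'ON'
    Cdc11: 'ON'
    GAP: 'ON'
    Spg1: 'OFF'
    Cdc7: 'OFF'
    Sid2_Mob1: 'OFF'
    Sid1_Cdc14: 'OFF'
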