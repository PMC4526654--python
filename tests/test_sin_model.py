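"""The reference SIN reconstruction: behavioral constraints, scoring, edits.

The behavioral constraint suite pins the model's stage-resolved steady
states and mutant verdicts one by one; it is the certification of the
bundled rule set, so these tests are deliberately literal.
"""

import pytest

from sinboole.dynamics import find_attractors
from sinboole.experiments import (
    ExperimentSpec,
    knockout,
    overexpression,
    run_experiment,
    stage_clamps,
    validate_stage_inputs,
)
from sinboole.logic_core import (
    expressions_equivalent,
    parse_rules,
    truth_table,
    validate,
)
from sinboole.sin_model import (
    SCORING_SET,
    enumerate_rule_edits,
    enumerate_single_edge_edits,
    hill_climb,
    score_model,
    training_specs,
)
from sinboole.logic_core import Const


class TestModelStructure:
    def test_sixteen_nodes_five_inputs(self, sin):
        assert len(sin.nodes) == 16
        assert sin.inputs == {"CDK-L", "CDK-H", "CDK-0", "Ppc89", "Cdc42"}

    def test_validates_clean_and_cdk_unregulated(self, sin):
        assert validate(sin).ok
        validate_stage_inputs(sin)  # CDK nodes are inputs: zero in-degree

    def test_gap_dominates_spg1_exhaustively(self, sin):
        # the GTPase rule must output 0 whenever the GAP is present, over
        # the full truth table of its regulators
        expr = sin.rules["Spg1"]
        regs = sorted(expr.variables())
        assert "GAP" in regs
        gap_bit = regs.index("GAP")
        for i, value in enumerate(truth_table(expr, regs)):
            if (i >> gap_bit) & 1:
                assert value == 0


class TestBehavioralConstraints:
    """Each test is one steady-state/verdict assertion of the certified model."""

    def test_c1_interphase_unique_nonseptating_gap_on(self, sin):
        result = run_experiment(sin, ExperimentSpec("interphase"))
        assert len(result.attractors) == 1 and result.attractors[0].is_fixed_point
        assert result.summary["GAP"] == "ON"
        assert result.summary["Sid4"] == result.summary["Cdc11"] == "ON"
        assert not result.septating

    def test_c2_early_mitosis_signaling_without_sid1(self, sin):
        result = run_experiment(sin, ExperimentSpec("early_mitosis"))
        assert len(result.attractors) == 1 and result.attractors[0].is_fixed_point
        s = result.summary
        assert s["Cdc16"] == "OFF"
        assert all(s[k] == "ON" for k in ("Plo1", "Spg1", "Cdc7", "Sid2_Mob1"))
        assert s["Sid1_Cdc14"] == "OFF"
        assert not result.septating

    def test_c3_late_mitosis_two_spb_like_states(self, sin):
        result = run_experiment(sin, ExperimentSpec("late_mitosis"))
        assert len(result.attractors) == 2
        assert all(a.is_fixed_point for a in result.attractors)
        by_gap = {a.states[0]["GAP"]: a.states[0] for a in result.attractors}
        old, new = by_gap[1], by_gap[0]
        # old SPB: only Plo1 active among SIN components
        assert old["Plo1"] == 1
        assert all(old[k] == 0 for k in ("Spg1", "Cdc7", "Sid1_Cdc14", "Sid2_Mob1"))
        # new SPB: the whole cascade fires
        assert all(new[k] == 1 for k in ("Spg1", "Cdc7", "Sid1_Cdc14", "Sid2_Mob1"))

    def test_c4_gap_clamp_abolishes_old_spb_state(self, sin):
        clamps = dict(stage_clamps("late_mitosis", sin), GAP=0)
        atts = find_attractors(sin, clamps)
        assert len(atts) == 1
        assert atts[0].states[0]["Sid1_Cdc14"] == 1

    @pytest.mark.parametrize("stage", ["interphase", "early_mitosis", "late_mitosis"])
    def test_c5_cdc11_ko_blocks_septation_all_stages(self, sin, stage):
        assert not run_experiment(sin, ExperimentSpec(stage, (knockout("Cdc11"),))).septating

    @pytest.mark.parametrize("gene", ["Byr4", "Cdc16"])
    def test_c6_gap_subunit_kos_septate_in_interphase(self, sin, gene):
        assert run_experiment(sin, ExperimentSpec("interphase", (knockout(gene),))).septating

    @pytest.mark.parametrize("gene", ["Spg1", "Cdc7"])
    def test_c7_cascade_kos_fail_and_spg1_stays_upstream(self, sin, gene):
        for stage in ("interphase", "early_mitosis", "late_mitosis"):
            assert not run_experiment(sin, ExperimentSpec(stage, (knockout(gene),))).septating
        eM = run_experiment(sin, ExperimentSpec("early_mitosis", (knockout("Cdc7"),)))
        assert eM.summary["Spg1"] == "ON"

    def test_c8_cdc11_cdc16_double_ko_non_septating(self, sin):
        spec = ExperimentSpec("late_mitosis", (knockout("Cdc11"), knockout("Cdc16")))
        assert not run_experiment(sin, spec).septating

    @pytest.mark.parametrize("gene", ["Spg1", "Cdc11", "Sid4"])
    def test_c9_cdc7_oe_rescues_cascade_and_scaffold_kos(self, sin, gene):
        spec = ExperimentSpec("late_mitosis", (knockout(gene), overexpression("Cdc7")))
        assert run_experiment(sin, spec).septating

    def test_c10_byr4_sid4_double_ko_non_septating(self, sin):
        spec = ExperimentSpec("late_mitosis", (knockout("Byr4"), knockout("Sid4")))
        assert not run_experiment(sin, spec).septating


class TestNuc2Variant:
    def test_differs_in_one_added_node_one_changed_rule(self, sin, nuc2_variant):
        assert set(nuc2_variant.nodes) - set(sin.nodes) == {"Nuc2"}
        changed = [
            n
            for n in sin.rules
            if not expressions_equivalent(sin.rules[n], nuc2_variant.rules[n])
        ]
        assert changed == ["GAP"]

    def test_variant_wt_interphase_single_inactive_state(self, nuc2_variant):
        result = run_experiment(nuc2_variant, ExperimentSpec("interphase"))
        assert len(result.attractors) == 1
        assert not result.septating

    def test_nuc2_ko_interphase_two_steady_states(self, nuc2_variant):
        result = run_experiment(
            nuc2_variant, ExperimentSpec("interphase", (knockout("Nuc2"),))
        )
        assert len(result.attractors) == 2
        assert all(a.is_fixed_point for a in result.attractors)
        verdicts = sorted(
            "septating" if a.states[0]["Sid1_Cdc14"] and a.states[0]["Sid2_Mob1"]
            else "inactive"
            for a in result.attractors
        )
        assert verdicts == ["inactive", "septating"]


class TestScoring:
    def test_reference_model_scores_perfectly(self, sin, training_expectations):
        score = score_model(sin, training_expectations)
        assert score.perfect
        assert score.max_total == 18 * 7  # 6 experiments x 3 stages x 7 nodes

    def test_expectation_table_covers_training_panel(self, training_expectations):
        assert len(training_expectations) == 18
        for row in training_expectations:
            assert set(row.expected) == set(SCORING_SET)

    def test_corrupted_rule_scores_strictly_lower(self, sin, training_expectations):
        broken = sin.with_rule("Spg1", Const(0))
        assert score_model(broken, training_expectations).total < 18 * 7

    def test_empty_expectations_score_zero(self, sin):
        score = score_model(sin, [])
        assert score.total == score.max_total == 0

    def test_missing_scoring_node_rejected(self, training_expectations):
        net = parse_rules("A := A")
        with pytest.raises(ValueError, match="scoring-set"):
            score_model(net, training_expectations)

    def test_row_removal_never_increases_total(self, sin, training_expectations):
        broken = sin.with_rule("Spg1", Const(0))
        full = score_model(broken, training_expectations).total
        for drop in range(len(training_expectations)):
            subset = [r for i, r in enumerate(training_expectations) if i != drop]
            assert score_model(broken, subset).total <= full


class TestEditEnumeration:
    def test_single_literal_negation_is_among_candidates(self):
        net = parse_rules("input B\nA := B")
        edits = enumerate_rule_edits(net)
        assert ("A", parse_rules("input B\nA := NOT B").rules["A"]) in edits

    def test_every_candidate_differs_in_exactly_one_rule(self, sin):
        for cand in enumerate_single_edge_edits(sin)[::25]:
            changed = [
                n for n in sin.rules if cand.rules[n] != sin.rules[n]
            ]
            assert len(changed) == 1

    def test_candidates_all_validate(self, sin):
        for cand in enumerate_single_edge_edits(sin)[::40]:
            assert validate(cand).ok or validate(cand).warnings

    def test_enumeration_is_deterministic(self, sin):
        a = enumerate_rule_edits(sin)
        b = enumerate_rule_edits(sin)
        assert a == b


def test_training_specs_are_wt_plus_five_kos():
    specs = training_specs()
    assert len(specs) == 18
    ids = {s.experiment_id for s in specs}
    assert ids == {"WT", "cdc11 KO", "spg1 KO", "cdc16 KO", "byr4 KO", "cdc7 KO"}


def test_hill_climb_restores_a_hand_corrupted_model(sin, training_expectations):
    from sinboole.logic_core import Not, Var

    broken = sin.with_rule("Cdc7", Not(Var("GAP")))
    assert not score_model(broken, training_expectations).perfect
    recovered, score = hill_climb(broken, training_expectations)
    assert score.perfect
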